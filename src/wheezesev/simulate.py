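"""Synthetic cohorts with the structure the severity analysis assumes.

One latent severity factor drives four ordinal indicators through a
threshold (latent-response) mechanism; covariates shift the factor; distal
outcomes follow a probit index in the factor; missingness can depend on
covariates (missing at random); repeated waves share a correlated factor
and within-item residual correlations; schools add a cluster-level
intercept.  Every draw is reproducible from (config, seed), and the truth
record keeps all generating parameters so any pipeline stage can be tested
for parameter recovery.

Default thresholds target the category proportions of an infant cohort of
ever-wheezers (episodes .32/.52/.12/.04, sleep .72/.13/.15, speech .18,
exercise .10 endorsed, renormalized over observed cases); default covariate
prevalences follow the same cohort's descriptive table, and the default
female-male factor difference is -0.20 SD.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .items import (
    EHAAS_ITEMS,
    ISAAC_ITEMS,
    MISSING,
    DesignMatrix,
    ItemResponseTable,
    OrdinalItemSpec,
)

# category proportions among observed responses (ever-wheezing infants, year 1)
DEFAULT_MARGINALS: dict[str, tuple[float, ...]] = {
    "episodes": (205 / 634, 328 / 634, 73 / 634, 28 / 634),
    "sleep": (455 / 634, 83 / 634, 96 / 634),
    "speech": (517 / 633, 116 / 633),
    "exercise": (576 / 643, 67 / 643),
}

DEFAULT_PREVALENCES: dict[str, float] = {
    "maternal_asthma": 0.23,
    "prenatal_smoking": 0.21,
    "single_mother": 0.44,
    "medicaid": 0.57,
    "cesarean": 0.34,
    "female": 0.38,
    "race_black": 0.25,
    "race_other": 0.09,
}


def thresholds_from_marginals(props: Sequence[float]) -> np.ndarray:
    """Invert the standard normal CDF at cumulative category proportions."""
    p = np.asarray(props, dtype=float)
    cum = np.cumsum(p)[:-1] / p.sum()
    if (np.diff(cum) <= 0).any() or cum[0] <= 0 or cum[-1] >= 1:
        raise ValueError("infeasible marginal targets (non-monotone cumulative)")
    return ndtri(cum)


@dataclass
class OutcomeSpec:
    """A distal ordinal outcome driven by the factor via a probit index."""

    name: str = "outcome"
    beta: float = 0.7            # factor effect on the outcome's y* scale
    marginals: tuple[float, ...] = (0.75, 0.25)
    gamma_x: dict[str, float] = field(default_factory=dict)  # direct covariate effects


@dataclass
class ClusterSpec:
    n_schools: int = 282
    icc: float = 0.1
    n_sites: int = 3
    site_shifts: tuple[float, ...] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not 0 <= self.icc <= 0.5:
            raise ValueError("ICC outside [0, 0.5]")
        if self.n_schools < 20:
            raise ValueError("need >= 20 schools")


@dataclass
class SimConfig:
    """Generative truth for a synthetic cohort."""

    n: int = 2000
    seed: int = 0
    loadings: tuple[float, ...] = (0.8, 0.7, 0.6, 0.5)
    marginals: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_MARGINALS)
    )
    covariates: dict[str, float] = field(default_factory=dict)  # name -> prevalence
    gamma: dict[str, float] = field(default_factory=dict)  # factor-on-covariate (SD units)
    outcome: OutcomeSpec | None = None
    missing: dict[str, tuple[float, dict[str, float]]] = field(default_factory=dict)
    waves: int = 1
    wave_cor: float = 0.6
    resid_cross: float = 0.2  # same-item residual correlation across waves
    noninvariance: dict[str, dict[int, float]] = field(default_factory=dict)
    clustering: ClusterSpec | None = None

    def __post_init__(self) -> None:
        lam = np.asarray(self.loadings)
        if (np.abs(lam) >= 1).any():
            raise ValueError("loadings must lie in (-1, 1)")
        if self.waves not in (1, 2):
            raise ValueError("waves must be 1 or 2")
        for base, _ in self.missing.values():
            if not 0 <= base < 1:
                raise ValueError("missing rates must lie in [0, 1)")

    @property
    def item_names(self) -> list[str]:
        return list(self.marginals)


@dataclass
class SimulatedStudy:
    config: SimConfig
    tables: dict[str, ItemResponseTable]  # keyed by wave label ('w1', 'w2')
    joint_table: ItemResponseTable | None
    X: DesignMatrix | None
    truth: dict
    eta: np.ndarray | None = None    # n x waves latent factor draws
    ystar: np.ndarray | None = None  # n x p latent responses, wave 1

    @property
    def table(self) -> ItemResponseTable:
        return self.tables["w1"]


def cohort1_config(n: int = 657, seed: int = 0, **kw) -> SimConfig:
    """Convenience config emulating the infant-cohort structure."""
    kw.setdefault("covariates", dict(DEFAULT_PREVALENCES))
    kw.setdefault("gamma", {"female": -0.20})
    return SimConfig(n=n, seed=seed, **kw)


def inject_noninvariance(
    config: SimConfig, component: str, deltas: dict[int, float]
) -> SimConfig:
    """Shift wave/group-2 measurement parameters by the given deltas.

    ``component`` is 'loadings', 'thresholds' (delta added to every
    threshold of the item) or 'residuals' (delta added to the residual
    variance).  The returned config carries the updated truth.
    """
    if component not in ("loadings", "thresholds", "residuals"):
        raise ValueError(f"unknown component {component!r}")
    cfg = copy.deepcopy(config)
    lam = np.asarray(cfg.loadings)
    if component == "loadings":
        for i, d in deltas.items():
            if not -1 < lam[i] + d < 1:
                raise ValueError("loading delta leaves (-1, 1)")
    if component == "residuals":
        for i, d in deltas.items():
            if 1 - lam[i] ** 2 + d <= 0:
                raise ValueError("residual delta implies non-positive variance")
    ni = copy.deepcopy(cfg.noninvariance)
    ni[component] = {int(k): float(v) for k, v in deltas.items()}
    cfg.noninvariance = ni
    return cfg


def _draw_covariates(cfg: SimConfig, rng) -> tuple[DesignMatrix | None, np.ndarray]:
    if not cfg.covariates:
        return None, np.zeros((cfg.n, 0))
    names = list(cfg.covariates)
    X = np.column_stack(
        [rng.binomial(1, cfg.covariates[c], size=cfg.n).astype(float) for c in names]
    )
    return DesignMatrix(names=names, X=X), X


def _wave_params(cfg: SimConfig, wave: int):
    """(loadings, thresholds dict, residual sds) for one wave, with any
    injected noninvariance applied to wave 2."""
    lam = np.asarray(cfg.loadings, dtype=float).copy()
    tau = {v: thresholds_from_marginals(p) for v, p in cfg.marginals.items()}
    resid_var = 1.0 - lam**2
    if wave == 2:
        ni = cfg.noninvariance
        for i, d in ni.get("loadings", {}).items():
            lam[i] += d
        for i, d in ni.get("thresholds", {}).items():
            v = list(tau)[i]
            tau[v] = tau[v] + d
        resid_var = 1.0 - lam**2
        for i, d in ni.get("residuals", {}).items():
            resid_var[i] += d
    return lam, tau, np.sqrt(resid_var)


def generate_cohort(config: SimConfig) -> SimulatedStudy:
    """Draw a cohort (and optional second wave / outcome / clusters).

    The latent severity factor is eta = x'gamma + zeta with unit residual
    variance; each latent response is y*_i = lambda_i eta + eps_i with unit
    conditional variance (delta parameterization), cut at the item
    thresholds.  Outcomes are drawn from a probit index beta*eta + x'gamma_out.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    design, X = _draw_covariates(cfg, rng)
    gvec = np.array([cfg.gamma.get(c, 0.0) for c in (design.names if design else [])])
    lin = X @ gvec if design else np.zeros(n)

    # factor(s)
    if cfg.waves == 1:
        zeta = rng.standard_normal((n, 1))
    else:
        r = cfg.wave_cor
        L = np.linalg.cholesky(np.array([[1.0, r], [r, 1.0]]))
        zeta = rng.standard_normal((n, 2)) @ L.T
    eta = lin[:, None] + zeta  # n x waves

    cluster_df = None
    school_effect = np.zeros(n)
    site_shift = np.zeros(n)
    if cfg.clustering is not None:
        cl = cfg.clustering
        school = rng.integers(0, cl.n_schools, size=n)
        site = school % cl.n_sites
        u = rng.normal(0.0, np.sqrt(cl.icc), size=cl.n_schools)
        school_effect = u[school]
        shifts = np.asarray(cl.site_shifts)
        site_shift = shifts[site]
        cluster_df = pd.DataFrame({"school": school.astype(str), "site": site.astype(str)})

    item_names = cfg.item_names
    specs = _specs_for(cfg)
    tables: dict[str, ItemResponseTable] = {}
    joint_codes: dict[str, np.ndarray] = {}
    truth_waves = {}
    eps_prev = None
    for w in range(1, cfg.waves + 1):
        lam, tau, resid_sd = _wave_params(cfg, w)
        eps = rng.standard_normal((n, len(item_names)))
        if w == 2 and cfg.resid_cross:
            rc = cfg.resid_cross
            eps = rc * eps_prev + np.sqrt(1 - rc**2) * eps
        eps_prev = eps
        codes = {}
        ystar_w = np.empty((n, len(item_names)))
        for i, v in enumerate(item_names):
            ystar = lam[i] * eta[:, w - 1] + resid_sd[i] * eps[:, i]
            if cfg.clustering is not None:
                icc = cfg.clustering.icc
                ystar = np.sqrt(1 - icc) * ystar + school_effect + site_shift
            ystar_w[:, i] = ystar
            codes[v] = np.digitize(ystar, tau[v]).astype(np.int64)
        if w == 1:
            ystar_wave1 = ystar_w
        ids = np.array([f"c{i}" for i in range(n)])
        tables[f"w{w}"] = ItemResponseTable(
            ids=ids,
            specs={s.name: s for s in specs},
            codes=codes,
            covariates=pd.DataFrame(X, columns=design.names) if design else None,
            cluster_ids=cluster_df,
            wave=f"w{w}",
        )
        joint_codes.update({f"{v}_w{w}": c for v, c in codes.items()})
        truth_waves[f"w{w}"] = {
            "loadings": lam.tolist(),
            "thresholds": {v: tau[v].tolist() for v in item_names},
            "resid_sd": resid_sd.tolist(),
        }

    outcome_truth = None
    if cfg.outcome is not None:
        o = cfg.outcome
        tau_o = thresholds_from_marginals(o.marginals)
        gox = np.array([o.gamma_x.get(c, 0.0) for c in (design.names if design else [])])
        idx = o.beta * eta[:, -1] + (X @ gox if design else 0.0)
        resid = np.sqrt(max(1e-12, 1.0 - o.beta**2))
        ystar_o = idx + resid * rng.standard_normal(n)
        oc = np.digitize(ystar_o, tau_o).astype(np.int64)
        ospec = OrdinalItemSpec(o.name, tuple(f"L{k}" for k in range(len(o.marginals))))
        last = tables[f"w{cfg.waves}"]
        last.specs[o.name] = ospec
        last.codes[o.name] = oc
        outcome_truth = {
            "beta": o.beta,
            "thresholds": tau_o.tolist(),
            "gamma_x": o.gamma_x,
            "resid_sd_given_eta": resid,
        }

    joint = None
    if cfg.waves == 2:
        jspecs = {}
        for w in (1, 2):
            for s in specs:
                jspecs[f"{s.name}_w{w}"] = OrdinalItemSpec(
                    f"{s.name}_w{w}", s.categories
                )
        joint = ItemResponseTable(
            ids=np.array([f"c{i}" for i in range(n)]),
            specs=jspecs,
            codes=joint_codes,
            covariates=pd.DataFrame(X, columns=design.names) if design else None,
            cluster_ids=cluster_df,
        )

    truth = {
        "gamma": {c: cfg.gamma.get(c, 0.0) for c in (design.names if design else [])},
        "waves": truth_waves,
        "wave_cor": cfg.wave_cor if cfg.waves == 2 else None,
        "outcome": outcome_truth,
        "clustering": None if cfg.clustering is None else {
            "icc": cfg.clustering.icc,
            "site_shifts": list(cfg.clustering.site_shifts),
        },
    }
    study = SimulatedStudy(config=cfg, tables=tables, joint_table=joint,
                           X=design, truth=truth, eta=eta, ystar=ystar_wave1)
    if cfg.missing:
        study = apply_mar_missingness(study)
    return study


def _specs_for(cfg: SimConfig) -> list[OrdinalItemSpec]:
    known = {s.name: s for s in ISAAC_ITEMS}
    ehaas = {s.name: s for s in EHAAS_ITEMS}
    out = []
    for v, props in cfg.marginals.items():
        c = len(props)
        if v in known and known[v].n_categories == c:
            out.append(known[v])
        elif v in ehaas and ehaas[v].n_categories == c:
            out.append(ehaas[v])
        else:
            out.append(OrdinalItemSpec(v, tuple(f"L{k}" for k in range(c))))
    return out


def apply_mar_missingness(study: SimulatedStudy) -> SimulatedStudy:
    """Blank item responses at covariate-dependent rates.

    Rates are additive in probability: item -> (base_rate, {covariate:
    added_points}).  Missingness depends on covariates only, never on the
    latent responses, so it is missing at random by construction.
    """
    cfg = study.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 911]))
    X = study.X.X if study.X is not None else np.zeros((cfg.n, 0))
    names = study.X.names if study.X is not None else []
    for table in list(study.tables.values()) + (
        [study.joint_table] if study.joint_table is not None else []
    ):
        for item, (base, shifts) in cfg.missing.items():
            cols = [c for c in table.codes if c == item or c.startswith(item + "_w")]
            for col in cols:
                p = np.full(cfg.n, base)
                for cov, d in shifts.items():
                    p = p + d * X[:, names.index(cov)]
                p = np.clip(p, 0.0, 0.95)
                if p.mean() >= 0.6:
                    raise ValueError("expected missingness >= 60%; degenerate model")
                mask = rng.random(cfg.n) < p
                table.codes[col] = np.where(mask, MISSING, table.codes[col])
    return study


def generate_clustered(config: SimConfig) -> SimulatedStudy:
    """Cohort with school/site clustering (config.clustering required)."""
    if config.clustering is None:
        raise ValueError("config.clustering must be set")
    return generate_cohort(config)


def subseed(master: int, replication: int) -> int:
    """Derive a per-replication seed below 2^31 from a master seed."""
    return int(np.random.SeedSequence([master, replication]).generate_state(1)[0] % (2**31))
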