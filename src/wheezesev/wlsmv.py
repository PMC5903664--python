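"""Diagonally weighted least squares estimation for the one-factor probit model.

The measurement model is a single latent severity factor with four ordinal
indicators under the delta parameterization: every latent response y* has
unit variance conditional on covariates, the factor has unit variance and
zero mean in the (first) group, and all loadings are free.  Structural
extensions regress the factor on covariates, and distal outcomes on the
factor plus direct covariate effects.

Estimation minimizes the diagonally weighted quadratic form

    F(theta) = (s - sigma(theta))' diag(W)^{-1} (s - sigma(theta)),

where s stacks stage-1 thresholds, probit slopes and polychoric
correlations and W is the diagonal of their asymptotic covariance.  Model
fit is judged by a mean- and variance-adjusted chi-square whose first two
moments match the chi-square reference with the model's degrees of freedom,
with RMSEA/CFI computed from it; parameter uncertainty uses the full
sandwich covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import brentq, least_squares
from scipy.stats import chi2 as chi2_dist
from scipy.stats import ncx2

from .polychoric import PolychoricSummary, assemble_summary, cluster_robust_gamma

LADDER_STEPS = ("configural", "loadings", "thresholds", "residuals")


@dataclass(frozen=True)
class ModelSpec:
    """Structure of a latent wheezing severity model.

    ``item_cats`` are the category counts of the factor indicators;
    ``outcome_cats`` adds one distal outcome regressed on the factor and
    directly on the modeled covariates.  ``q_factor`` covariates predict the
    factor; ``q_direct`` covariates (listed first in the design matrix, e.g.
    study-site dummies in the multilevel approximation) get free saturated
    slopes on every variable.  ``groups`` selects a two-group invariance
    step; thresholds are saturated except where the step constrains them.
    """

    item_cats: tuple[int, ...] = (4, 3, 2, 2)
    outcome_cats: int | None = None
    q_factor: int = 0
    q_direct: int = 0
    groups: str | None = None  # None or a LADDER_STEPS entry
    multilevel: bool = False

    def __post_init__(self) -> None:
        if self.groups is not None and self.groups not in LADDER_STEPS:
            raise ValueError(f"unknown invariance step {self.groups!r}")
        if self.groups is not None and self.outcome_cats is not None:
            raise ValueError("two-group models with distal outcomes unsupported")
        if any(c < 2 for c in self.item_cats):
            raise ValueError("items need >= 2 categories")

    @property
    def n_items(self) -> int:
        return len(self.item_cats)

    @property
    def var_cats(self) -> tuple[int, ...]:
        if self.outcome_cats is None:
            return self.item_cats
        return self.item_cats + (self.outcome_cats,)

    @property
    def p(self) -> int:
        return len(self.var_cats)

    @property
    def q(self) -> int:
        return self.q_factor + self.q_direct

    @property
    def n_groups(self) -> int:
        return 1 if self.groups is None else 2

    # ---- bookkeeping ----------------------------------------------------

    def n_stats(self) -> int:
        per_group = (
            sum(c - 1 for c in self.var_cats)
            + self.p * self.q
            + self.p * (self.p - 1) // 2
        )
        return per_group * self.n_groups

    def param_names(self) -> list[str]:
        """Free parameters under the documented identification convention."""
        p_ind = self.n_items
        names: list[str] = []
        if self.groups is None:
            for i, c in enumerate(self.var_cats):
                names += [f"tau[{i},{k}]" for k in range(c - 1)]
            names += [f"lambda[{i}]" for i in range(p_ind)]
            if self.outcome_cats is not None:
                names += ["beta"]
            names += [f"gamma[{r}]" for r in range(self.q_factor)]
            if self.outcome_cats is not None:
                names += [f"kappa[{r}]" for r in range(self.q_factor)]
            for v in range(self.p):
                names += [f"direct[{v},{d}]" for d in range(self.q_direct)]
            return names

        step = self.groups
        # thresholds: saturated per group except when constrained equal
        if step in ("configural", "loadings"):
            for g in (1, 2):
                for i, c in enumerate(self.item_cats):
                    names += [f"tau{g}[{i},{k}]" for k in range(c - 1)]
        else:
            for i, c in enumerate(self.item_cats):
                names += [f"tau[{i},{k}]" for k in range(c - 1)]
        if step == "configural":
            names += [f"lambda1[{i}]" for i in range(p_ind)]
            names += [f"lambda2[{i}]" for i in range(p_ind)]
        else:
            names += [f"lambda[{i}]" for i in range(p_ind)]
        for g in (1, 2):
            names += [f"gamma{g}[{r}]" for r in range(self.q_factor)]
        if step != "configural":
            names += ["psi2"]
        if step in ("thresholds",):
            names += ["alpha2"] + [f"delta2[{i}]" for i in range(p_ind)]
        elif step == "residuals":
            names += ["alpha2"]  # scale factors re-fixed by the constraint
        return names

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "item_cats": list(self.item_cats),
                "outcome_cats": self.outcome_cats,
                "q_factor": self.q_factor,
                "q_direct": self.q_direct,
                "groups": self.groups,
                "multilevel": self.multilevel,
            }
        )

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        try:
            d = yaml.safe_load(text)
            return cls(
                item_cats=tuple(d.get("item_cats", (4, 3, 2, 2))),
                outcome_cats=d.get("outcome_cats"),
                q_factor=int(d.get("q_factor", 0)),
                q_direct=int(d.get("q_direct", 0)),
                groups=d.get("groups"),
                multilevel=bool(d.get("multilevel", False)),
            )
        except (yaml.YAMLError, TypeError, KeyError, ValueError) as e:
            raise ValueError(f"invalid model spec YAML: {e}") from e


def count_df(spec: ModelSpec, check_identification: bool = True) -> int:
    """Degrees of freedom: modeled statistics minus free parameters.

    Saturated thresholds and saturated direct slopes cancel between the two
    counts; a saturated between level contributes nothing.  Raises for
    under-identified specifications (negative df or rank-deficient model
    Jacobian).
    """
    df = spec.n_stats() - len(spec.param_names())
    if df < 0:
        raise ValueError(f"under-identified model: df = {df} < 0")
    if check_identification:
        sigma, x0, _, names = _build_model(spec, _fake_stats(spec))
        rng = np.random.default_rng(12345)
        th = x0 + 0.05 * rng.standard_normal(len(x0))
        J = _numjac(sigma, th)
        rank = np.linalg.matrix_rank(J, tol=1e-8)
        if rank < len(x0):
            raise ValueError(
                f"model not identified: Jacobian rank {rank} < {len(x0)} free parameters"
            )
    return df


# ---------------------------------------------------------------------------
# Model-implied statistics
# ---------------------------------------------------------------------------

def _pairs(p: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(p) for j in range(i + 1, p)]


def _fake_stats(spec: ModelSpec) -> list[dict]:
    """Plausible stage-1 values used only for identification checks."""
    out = []
    for _ in range(spec.n_groups):
        tau = [np.linspace(-0.5, 1.5, c - 1) for c in spec.var_cats]
        out.append({"tau": tau, "slopes": np.zeros((spec.p, spec.q))})
    return out


def _group_stage1(summary: PolychoricSummary, spec: ModelSpec) -> dict:
    tau = [summary.thresholds[v] for v in summary.var_names]
    slopes = np.zeros((spec.p, spec.q))
    if spec.q:
        slopes = np.vstack([summary.slopes[v] for v in summary.var_names])
    return {"tau": tau, "slopes": slopes}


def _build_model(spec: ModelSpec, stage1: list[dict]):
    """Return (sigma(theta), start values, bounds, parameter names).

    The statistic vector layout matches PolychoricSummary: thresholds, then
    slopes variable-major, then correlations for pairs (i < j); two-group
    models concatenate group 1 then group 2.
    """
    names = spec.param_names()
    idx = {nm: i for i, nm in enumerate(names)}
    p, q, qd, qf = spec.p, spec.q, spec.q_direct, spec.q_factor
    cats = spec.var_cats
    pairs = _pairs(p)
    n_tau = sum(c - 1 for c in cats)
    per_group = n_tau + p * q + len(pairs)
    has_out = spec.outcome_cats is not None
    i_out = p - 1 if has_out else None

    lo = np.full(len(names), -np.inf)
    hi = np.full(len(names), np.inf)
    x0 = np.zeros(len(names))
    for nm, i in idx.items():
        if nm.startswith("lambda") or nm == "beta":
            lo[i], hi[i], x0[i] = -0.999, 0.999, 0.7 if nm.startswith("lambda") else 0.0
        elif nm == "psi2":
            lo[i], x0[i] = 1e-6, 1.0
        elif nm.startswith("delta2"):
            lo[i], x0[i] = 1e-3, 1.0
    # start thresholds at their stage-1 values
    for g in range(spec.n_groups):
        st = stage1[g]
        for i, c in enumerate(cats):
            for k in range(c - 1):
                for cand in (f"tau{g+1}[{i},{k}]", f"tau[{i},{k}]"):
                    if cand in idx:
                        x0[idx[cand]] = st["tau"][i][k]
                        break
        for v in range(p):
            for d in range(qd):
                if f"direct[{v},{d}]" in idx:
                    x0[idx[f"direct[{v},{d}]"]] = st["slopes"][v, d]

    def sigma(theta: np.ndarray) -> np.ndarray:
        t = {nm: theta[i] for nm, i in idx.items()}
        out = np.zeros(per_group * spec.n_groups)
        for g in range(1, spec.n_groups + 1):
            off = (g - 1) * per_group
            if spec.groups is None:
                lam = np.array([t[f"lambda[{i}]"] for i in range(spec.n_items)])
                load = np.append(lam, t["beta"]) if has_out else lam
                psi, alpha, delta = 1.0, 0.0, np.ones(p)
                gam = np.array([t[f"gamma[{r}]"] for r in range(qf)])
            else:
                step = spec.groups
                if step == "configural":
                    lam = np.array([t[f"lambda{g}[{i}]"] for i in range(spec.n_items)])
                else:
                    lam = np.array([t[f"lambda[{i}]"] for i in range(spec.n_items)])
                load = lam
                psi = 1.0 if (g == 1 or step == "configural") else t["psi2"]
                alpha = 0.0
                delta = np.ones(p)
                if g == 2 and step == "thresholds":
                    alpha = t["alpha2"]
                    delta = np.array([t[f"delta2[{i}]"] for i in range(p)])
                elif g == 2 and step == "residuals":
                    alpha = t["alpha2"]
                    # residual variances equal across groups fixes the scale
                    # factors: theta_i = 1 - lam_i^2 (group 1) for group 2 too
                    delta = 1.0 / np.sqrt(np.clip(1.0 - lam**2 + lam**2 * psi, 1e-8, None))
                gam = np.array([t[f"gamma{g}[{r}]"] for r in range(qf)])
            # thresholds
            pos = off
            for i, c in enumerate(cats):
                for k in range(c - 1):
                    for cand in (f"tau{g}[{i},{k}]", f"tau[{i},{k}]"):
                        if cand in idx:
                            tv = t[cand]
                            break
                    if spec.groups is not None and g == 2 and spec.groups in (
                        "thresholds", "residuals"
                    ):
                        tv = delta[i] * (tv - load[i] * alpha)
                    out[pos] = tv
                    pos += 1
            # slopes: direct columns first, then modeled columns
            for v in range(p):
                for d in range(qd):
                    out[pos] = t[f"direct[{v},{d}]"]
                    pos += 1
                for r in range(qf):
                    val = delta[v] * load[v] * gam[r]
                    if has_out and v == i_out:
                        val = t["beta"] * gam[r] + t[f"kappa[{r}]"]
                    out[pos] = val
                    pos += 1
            # correlations
            for (i, j) in pairs:
                out[pos] = load[i] * load[j] * psi * delta[i] * delta[j]
                pos += 1
        return out

    return sigma, x0, (lo, hi), names


def _numjac(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    f0 = f(x)
    J = np.zeros((len(f0), len(x)))
    for j in range(len(x)):
        xp = x.copy()
        xm = x.copy()
        xp[j] += eps
        xm[j] -= eps
        J[:, j] = (f(xp) - f(xm)) / (2 * eps)
    return J


# ---------------------------------------------------------------------------
# Fit machinery
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """A fitted model with its robust fit surface.

    ``chi2`` is the scaled-and-shifted statistic referenced to a chi-square
    with integer ``df``; ``chi2_mv``/``df_mv`` is the companion
    mean-variance-adjusted variant with estimated (fractional) degrees of
    freedom.
    """

    spec: ModelSpec
    param_names: list[str]
    theta: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    chi2: float
    df: int
    p: float
    chi2_mv: float
    df_mv: float
    p_mv: float
    rmsea: tuple[float, float, float]
    cfi: float
    T_raw: float
    trM: float
    trM2: float
    n: int
    converged: bool
    n_iter: int
    grad_norm: float
    s: np.ndarray = field(repr=False, default=None)
    w_diag: np.ndarray = field(repr=False, default=None)
    gamma: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)
    J: np.ndarray = field(repr=False, default=None)
    warnings: list[str] = field(default_factory=list)

    def __getitem__(self, name: str) -> float:
        return float(self.theta[self.param_names.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.se[self.param_names.index(name)])

    def ci_of(self, name: str, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm as _norm

        z = _norm.ppf(0.5 + level / 2)
        est, se = self[name], self.se_of(name)
        return est - z * se, est + z * se

    @property
    def loadings(self) -> np.ndarray:
        pre = "lambda1" if self.spec.groups == "configural" else "lambda"
        return np.array(
            [
                self.theta[i]
                for i, nm in enumerate(self.param_names)
                if nm.startswith(pre + "[")
            ]
        )

    def to_dict(self) -> dict:
        return {
            "estimates": dict(zip(self.param_names, self.theta.tolist())),
            "se": dict(zip(self.param_names, self.se.tolist())),
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
            "chi2_mv": self.chi2_mv,
            "df_mv": self.df_mv,
            "p_mv": self.p_mv,
            "rmsea": list(self.rmsea),
            "cfi": self.cfi,
            "n": self.n,
            "converged": self.converged,
            "warnings": self.warnings,
        }


def _stack_groups(summaries: Sequence[PolychoricSummary]):
    s = np.concatenate([m.s for m in summaries])
    w = np.concatenate([m.w_diag for m in summaries])
    dims = [len(m.s) for m in summaries]
    gamma = np.zeros((sum(dims), sum(dims)))
    off = 0
    for m, d in zip(summaries, dims):
        gamma[off : off + d, off : off + d] = m.gamma
        off += d
    return s, w, gamma


def robust_test(
    residuals: np.ndarray,
    J: np.ndarray,
    gamma: np.ndarray,
    w_diag: np.ndarray,
    df: int,
) -> dict:
    """Mean- and variance-adjusted goodness-of-fit statistics.

    Returns the scaled-and-shifted statistic (integer reference df) and the
    mean-variance-adjusted variant (estimated df), both with p-values, plus
    the trace terms used for difference testing.
    """
    Dinv = 1.0 / w_diag
    T = float(residuals @ (Dinv * residuals))
    if J.size:
        B = Dinv[:, None] * J
        A = J.T @ B
        try:
            Ainv_Bt = np.linalg.solve(A, B.T)
        except np.linalg.LinAlgError as e:
            raise ValueError("singular weight/Jacobian system in robust test") from e
        U = np.diag(Dinv) - B @ Ainv_Bt
    else:
        U = np.diag(Dinv)
    M = U @ gamma
    trM = float(np.trace(M))
    trM2 = float(np.sum(M * M.T))
    if not np.isfinite(trM) or not np.isfinite(trM2) or trM2 <= 0:
        if df == 0:
            return {"chi2": 0.0, "df": 0, "p": 1.0, "chi2_mv": 0.0, "df_mv": 0.0,
                    "p_mv": 1.0, "T_raw": T, "trM": 0.0, "trM2": 0.0, "U": U}
        raise ValueError("non-finite trace terms in robust test (singular weight)")
    if df == 0:
        return {"chi2": 0.0, "df": 0, "p": 1.0, "chi2_mv": 0.0, "df_mv": 0.0,
                "p_mv": 1.0, "T_raw": T, "trM": trM, "trM2": trM2, "U": U}
    chi2_ss = max(0.0, np.sqrt(df / trM2) * (T - trM) + df)
    p_ss = float(chi2_dist.sf(chi2_ss, df))
    df_mv = trM**2 / trM2
    chi2_mv = T * trM / trM2
    p_mv = float(chi2_dist.sf(chi2_mv, df_mv))
    return {"chi2": chi2_ss, "df": df, "p": p_ss, "chi2_mv": chi2_mv,
            "df_mv": df_mv, "p_mv": p_mv, "T_raw": T, "trM": trM, "trM2": trM2,
            "U": U}


def robust_se(J: np.ndarray, gamma: np.ndarray, w_diag: np.ndarray):
    """Sandwich covariance of the DWLS estimates and its sqrt-diagonal."""
    Dinv = 1.0 / w_diag
    B = Dinv[:, None] * J
    A = J.T @ B
    rank = np.linalg.matrix_rank(A, tol=1e-10)
    if rank < J.shape[1]:
        raise ValueError(f"rank-deficient Jacobian: rank {rank} < {J.shape[1]}")
    Ainv = np.linalg.inv(A)
    mid = B.T @ gamma @ B
    V = Ainv @ mid @ Ainv
    V = 0.5 * (V + V.T)
    return np.sqrt(np.clip(np.diag(V), 0, None)), V


def rmsea(chi2: float, df: int, n: int, *, ci: bool = True) -> tuple[float, float, float]:
    """Root mean square error of approximation with 90% confidence interval.

    point = sqrt(max(0, (chi2 - df) / (df * n))); the interval inverts the
    noncentral chi-square at 0.05 / 0.95.  Degenerate inputs return 0.
    """
    if df < 1 or n <= 1:
        return (0.0, 0.0, 0.0)
    point = float(np.sqrt(max(0.0, (chi2 - df) / (df * n))))
    if not ci:
        return (point, np.nan, np.nan)

    def _solve(prob):
        # find noncentrality nc with ncx2.cdf(chi2, df, nc) == prob
        if chi2_dist.cdf(chi2, df) < prob:
            return 0.0
        f = lambda nc: ncx2.cdf(chi2, df, nc) - prob
        hi = max(10.0, chi2 * 2)
        while f(hi) > 0 and hi < 1e7:
            hi *= 2
        return brentq(f, 1e-12, hi, xtol=1e-10)

    lo90 = float(np.sqrt(_solve(0.95) / (df * n)))
    hi90 = float(np.sqrt(_solve(0.05) / (df * n)))
    return (point, lo90, hi90)


def cfi(chi2: float, df: float, chi2_baseline: float, df_baseline: float) -> float:
    """Comparative fit index against the zero-correlation baseline model."""
    num = max(0.0, chi2 - df)
    den = max(chi2 - df, chi2_baseline - df_baseline, 0.0)
    if den == 0.0:
        return 1.0
    if chi2_baseline - df_baseline < chi2 - df:
        warnings.warn("baseline fits better than model; CFI < 1 unreliable")
    return float(np.clip(1.0 - num / den, 0.0, 1.0))


def _baseline_test(summaries: Sequence[PolychoricSummary], gamma: np.ndarray):
    """Fit surface of the independence baseline (correlations fixed at 0)."""
    s, w, _ = _stack_groups(summaries)
    Dinv = 1.0 / w
    mask = np.zeros(len(s), dtype=bool)
    off = 0
    for m in summaries:
        sl = m.stat_slices()["rho"]
        mask[off + sl.start : off + sl.stop] = True
        off += len(m.s)
    T_b = float(np.sum(s[mask] ** 2 * Dinv[mask]))
    df_b = int(mask.sum())
    U = np.zeros((len(s), len(s)))
    U[np.ix_(mask, mask)] = np.diag(Dinv[mask])
    M = U @ gamma
    trM = float(np.trace(M))
    trM2 = float(np.sum(M * M.T))
    chi2_b = max(0.0, np.sqrt(df_b / trM2) * (T_b - trM) + df_b)
    return chi2_b, df_b


def fit_dwls(
    summary: PolychoricSummary | Sequence[PolychoricSummary],
    spec: ModelSpec,
    *,
    gamma_override: np.ndarray | None = None,
) -> FitResult:
    """Fit a model by diagonally weighted least squares with robust statistics.

    ``summary`` is one PolychoricSummary, or a pair for two-group models.
    ``gamma_override`` substitutes a (cluster-robust) asymptotic covariance
    while keeping the weight vector.
    """
    summaries = [summary] if isinstance(summary, PolychoricSummary) else list(summary)
    if len(summaries) != spec.n_groups:
        raise ValueError(f"spec expects {spec.n_groups} group(s), got {len(summaries)}")
    for m in summaries:
        if m.p != spec.p:
            raise ValueError("summary variable count inconsistent with spec")
        if m.q != spec.q:
            raise ValueError("summary covariate count inconsistent with spec")
    stage1 = [_group_stage1(m, spec) for m in summaries]
    sigma, x0, (lo, hi), names = _build_model(spec, stage1)
    df = count_df(spec, check_identification=False)
    return fit_generic(summaries, spec, sigma, x0, (lo, hi), names, df,
                       gamma_override=gamma_override)


def fit_generic(
    summaries: Sequence[PolychoricSummary],
    spec: ModelSpec,
    sigma,
    x0: np.ndarray,
    bounds,
    names: list[str],
    df: int,
    *,
    gamma_override: np.ndarray | None = None,
) -> FitResult:
    """Optimize a model-implied statistic map against stacked summaries.

    Shared backend of :func:`fit_dwls` and the longitudinal invariance
    models, which supply their own sigma(theta)."""
    lo, hi = bounds
    s, w, gamma = _stack_groups(summaries)
    if gamma_override is not None:
        gamma = gamma_override
    if (w <= 0).any():
        raise ValueError("weight diagonal must be strictly positive")
    sw = np.sqrt(w)

    def wres(theta):
        return (sigma(theta) - s) / sw

    res = least_squares(
        wres, np.clip(x0, lo + 1e-9, hi - 1e-9), bounds=(lo, hi), method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-12, max_nfev=20000,
    )
    theta = res.x
    warns: list[str] = []
    lam_idx = [i for i, nm in enumerate(names) if nm.startswith("lambda") or nm == "beta"]
    if any(abs(theta[i]) >= 0.998 for i in lam_idx):
        warns.append("Heywood case: loading bounded at 0.999")
    r = s - sigma(theta)
    J = _numjac(sigma, theta)
    grad = 2.0 * (J.T @ (r / w))
    gnorm = float(np.linalg.norm(grad, np.inf))

    test = robust_test(r, J, gamma, w, df)
    se, V = robust_se(J, gamma, w)
    n = max(m.n for m in summaries) if spec.groups is None else sum(m.n for m in summaries)
    chi2_b, df_b = _baseline_test(summaries, gamma)
    cfi_val = cfi(test["chi2"], df, chi2_b, df_b)
    rm = rmsea(test["chi2"], df, n) if df >= 1 else (0.0, 0.0, 0.0)

    return FitResult(
        spec=spec,
        param_names=names,
        theta=theta,
        se=se,
        vcov=V,
        chi2=test["chi2"],
        df=df,
        p=test["p"],
        chi2_mv=test["chi2_mv"],
        df_mv=test["df_mv"],
        p_mv=test["p_mv"],
        rmsea=rm,
        cfi=cfi_val,
        T_raw=test["T_raw"],
        trM=test["trM"],
        trM2=test["trM2"],
        n=n,
        converged=bool(res.success and gnorm < 1e-6 * max(1.0, abs(test["T_raw"]))),
        n_iter=int(res.nfev),
        grad_norm=gnorm,
        s=s,
        w_diag=w,
        gamma=gamma,
        residuals=r,
        J=J,
        warnings=warns,
    )


def fit_multilevel_within(
    table,
    design_sites: np.ndarray,
    school_ids: np.ndarray,
    *,
    modeled_X: np.ndarray | None = None,
    item_cats: tuple[int, ...] | None = None,
) -> FitResult:
    """Within-schools factor model with a saturated between level.

    Approximates two-level weighted least squares: stage-1 statistics are
    estimated conditional on study-site dummies (free, saturated slopes),
    the asymptotic covariance is made cluster-robust over schools, and the
    between level contributes no degrees of freedom.
    """
    schools = np.asarray(school_ids)
    if len(np.unique(schools)) < 20:
        raise ValueError("need at least 20 schools for the cluster-robust step")
    q_direct = design_sites.shape[1]
    if modeled_X is not None and modeled_X.ndim == 1:
        modeled_X = modeled_X[:, None]
    X = design_sites if modeled_X is None else np.column_stack([design_sites, modeled_X])
    q_factor = 0 if modeled_X is None else modeled_X.shape[1]
    summary = assemble_summary(table, X, x_names=[f"x{j}" for j in range(X.shape[1])])
    gamma_cr = cluster_robust_gamma(summary, schools)
    summary.gamma = gamma_cr
    summary.w_diag = np.diag(gamma_cr).copy()
    cats = item_cats if item_cats is not None else tuple(summary.n_cats)
    spec = ModelSpec(item_cats=cats, q_factor=q_factor, q_direct=q_direct,
                     multilevel=True)
    return fit_dwls(summary, spec)


def format_fit_table(fits: dict[str, FitResult]) -> str:
    """Text block mirroring the published fit-index table layout."""
    lines = [f"{'Model':<22}{'chi2':>8}{'df':>5}{'p':>7}{'RMSEA':>7}{'90% CI':>14}{'CFI':>6}"]
    for name, f in fits.items():
        lo, hi = f.rmsea[1], f.rmsea[2]
        lines.append(
            f"{name:<22}{f.chi2:>8.2f}{f.df:>5d}{f.p:>7.2f}{f.rmsea[0]:>7.2f}"
            f"{f'[{lo:.2f}, {hi:.2f}]':>14}{f.cfi:>6.2f}"
        )
    return "\n".join(lines)
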