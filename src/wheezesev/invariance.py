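"""Measurement-invariance ladders and scaled chi-square difference tests.

A ladder holds the factor structure fixed while progressively constraining
measurement parameters across two groups (female/male children) or two
assessment waves: configural (all free), equal loadings, equal thresholds,
equal residual variances.  Each constraint step is paired with
identification releases under the delta parameterization -- constraining
loadings frees the group-2 factor variance, constraining thresholds frees
the group-2 scale factors and latent mean, constraining residual variances
re-fixes the scale factors -- the unique release pattern consistent with
the degrees-of-freedom sequence 46 -> 49 -> 51 -> 55 for the sex ladders
with seven covariates.

Longitudinal ladders model both waves jointly (correlated factors, free
within-child residual correlations between the same item across waves) so
the difference tests respect the repeated-measures dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .polychoric import PolychoricSummary
from .wlsmv import LADDER_STEPS, FitResult, ModelSpec, _numjac, fit_dwls, fit_generic


@dataclass
class DiffTestResult:
    """Scaled chi-square difference between two nested fits."""

    dchi2: float
    ddf: int
    p: float
    dchi2_first_order: float
    p_first_order: float
    negative_flag: bool = False


@dataclass
class InvarianceLadder:
    grouping: str
    steps: list[str]
    fits: list[FitResult]
    diffs: list[DiffTestResult] = field(default_factory=list)

    def df_sequence(self) -> list[int]:
        return [f.df for f in self.fits]

    def to_text(self) -> str:
        hdr = (f"{'Step':<12}{'chi2':>9}{'df':>5}{'p':>7}"
               f"{'dchi2':>9}{'ddf':>5}{'p_diff':>8}")
        lines = [f"Invariance ladder ({self.grouping})", hdr]
        for i, (st, f) in enumerate(zip(self.steps, self.fits)):
            if i == 0:
                lines.append(f"{st:<12}{f.chi2:>9.2f}{f.df:>5d}{f.p:>7.2f}"
                             f"{'-':>9}{'-':>5}{'-':>8}")
            else:
                d = self.diffs[i - 1]
                lines.append(f"{st:<12}{f.chi2:>9.2f}{f.df:>5d}{f.p:>7.2f}"
                             f"{d.dchi2:>9.2f}{d.ddf:>5d}{d.p:>8.2f}")
        return "\n".join(lines)


def _proj_U(fit: FitResult) -> np.ndarray:
    Dinv = 1.0 / fit.w_diag
    J = fit.J
    B = Dinv[:, None] * J
    A = J.T @ B
    return np.diag(Dinv) - B @ np.linalg.solve(A, B.T)


def scaled_diff_test(
    fit_free: FitResult, fit_restricted: FitResult, gamma: np.ndarray | None = None
) -> DiffTestResult:
    """Scaled likelihood-ratio-style test for nested DWLS fits.

    The raw difference of the weighted fit functions is referenced to the
    chi-square with ddf degrees of freedom after a moment correction built
    from the trace of the difference of residual-projection matrices times
    the asymptotic covariance.  The default statistic matches the first two
    moments (scale and shift); the first-order (mean-only) variant is also
    reported.  A negative corrected statistic is flagged and reported as 0.
    """
    if fit_restricted.df <= fit_free.df:
        raise ValueError("models not nested: restricted df must exceed free df")
    if fit_free.s.shape != fit_restricted.s.shape or not np.allclose(
        fit_free.s, fit_restricted.s
    ):
        raise ValueError("fits were not computed on the same statistic vector")
    ddf = fit_restricted.df - fit_free.df
    gamma = fit_free.gamma if gamma is None else gamma
    dT = fit_restricted.T_raw - fit_free.T_raw
    Md = (_proj_U(fit_restricted) - _proj_U(fit_free)) @ gamma
    trMd = float(np.trace(Md))
    trMd2 = float(np.sum(Md * Md.T))
    neg = dT < 0 or trMd <= 0 or trMd2 <= 0
    if neg:
        return DiffTestResult(0.0, ddf, 1.0, 0.0, 1.0, True)
    stat_ss = max(0.0, np.sqrt(ddf / trMd2) * (dT - trMd) + ddf)
    stat_fo = dT * ddf / trMd
    return DiffTestResult(
        dchi2=stat_ss,
        ddf=ddf,
        p=float(chi2_dist.sf(stat_ss, ddf)),
        dchi2_first_order=stat_fo,
        p_first_order=float(chi2_dist.sf(stat_fo, ddf)),
        negative_flag=False,
    )


def build_ladder(
    summaries: Sequence[PolychoricSummary],
    *,
    item_cats: tuple[int, ...] = (4, 3, 2, 2),
    q_factor: int = 0,
    grouping: str = "sex",
    grouping_covariate: str | None = None,
) -> InvarianceLadder:
    """Fit the four-step invariance ladder over two groups.

    ``summaries`` are the two group-wise stage-1 summaries (e.g. female and
    male children), estimated with the same covariate scheme; the grouping
    variable itself must not appear in that scheme.
    """
    if len(summaries) != 2:
        raise ValueError("ladder requires exactly 2 groups")
    for m in summaries:
        if grouping_covariate is not None and grouping_covariate in m.x_names:
            raise ValueError(
                f"covariate scheme contains the grouping variable {grouping_covariate!r}"
            )
        if m.q != q_factor:
            raise ValueError("summary covariate count inconsistent with q_factor")
    fits = []
    for step in LADDER_STEPS:
        spec = ModelSpec(item_cats=item_cats, q_factor=q_factor, groups=step)
        fits.append(fit_dwls(list(summaries), spec))
    diffs = [
        scaled_diff_test(fits[i], fits[i + 1]) for i in range(len(fits) - 1)
    ]
    return InvarianceLadder(grouping=grouping, steps=list(LADDER_STEPS),
                            fits=list(fits), diffs=diffs)


# ---------------------------------------------------------------------------
# Longitudinal (two-wave joint) ladder
# ---------------------------------------------------------------------------

def _longitudinal_model(step: str, item_cats: tuple[int, ...], q: int, stage1_tau):
    """sigma(theta) for the joint two-wave model (8 variables, one group).

    Correlated wave factors, per-wave covariate effects, and free residual
    correlations between the same item across waves.  Wave-2 identification
    releases mirror the two-group convention.
    """
    p_ind = len(item_cats)
    p = 2 * p_ind
    cats = tuple(item_cats) * 2
    names: list[str] = []
    if step in ("configural", "loadings"):
        for w in (1, 2):
            for i, c in enumerate(item_cats):
                names += [f"tau{w}[{i},{k}]" for k in range(c - 1)]
    else:
        for i, c in enumerate(item_cats):
            names += [f"tau[{i},{k}]" for k in range(c - 1)]
    if step == "configural":
        names += [f"lambda1[{i}]" for i in range(p_ind)]
        names += [f"lambda2[{i}]" for i in range(p_ind)]
    else:
        names += [f"lambda[{i}]" for i in range(p_ind)]
    for w in (1, 2):
        names += [f"gamma{w}[{r}]" for r in range(q)]
    names += ["phi12"] + [f"rcross[{i}]" for i in range(p_ind)]
    if step != "configural":
        names += ["psi2"]
    if step == "thresholds":
        names += ["alpha2"] + [f"delta2[{i}]" for i in range(p_ind)]
    elif step == "residuals":
        names += ["alpha2"]
    idx = {nm: i for i, nm in enumerate(names)}

    lo = np.full(len(names), -np.inf)
    hi = np.full(len(names), np.inf)
    x0 = np.zeros(len(names))
    for nm, i in idx.items():
        if nm.startswith(("lambda", "phi12", "rcross")):
            lo[i], hi[i] = -0.999, 0.999
            x0[i] = 0.7 if nm.startswith("lambda") else (0.5 if nm == "phi12" else 0.1)
        elif nm == "psi2":
            lo[i], x0[i] = 1e-6, 1.0
        elif nm.startswith("delta2"):
            lo[i], x0[i] = 1e-3, 1.0
    for w in (1, 2):
        for i, c in enumerate(item_cats):
            for k in range(c - 1):
                for cand in (f"tau{w}[{i},{k}]", f"tau[{i},{k}]"):
                    if cand in idx:
                        x0[idx[cand]] = stage1_tau[(w - 1) * p_ind + i][k]
                        break

    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]

    def sigma(theta):
        t = {nm: theta[i] for nm, i in idx.items()}
        if step == "configural":
            lam = [np.array([t[f"lambda1[{i}]"] for i in range(p_ind)]),
                   np.array([t[f"lambda2[{i}]"] for i in range(p_ind)])]
        else:
            shared = np.array([t[f"lambda[{i}]"] for i in range(p_ind)])
            lam = [shared, shared]
        psi = [1.0, 1.0 if step == "configural" else t["psi2"]]
        alpha = [0.0, t.get("alpha2", 0.0) if step in ("thresholds", "residuals") else 0.0]
        if step == "thresholds":
            delta2 = np.array([t[f"delta2[{i}]"] for i in range(p_ind)])
        elif step == "residuals":
            delta2 = 1.0 / np.sqrt(
                np.clip(1.0 - lam[1] ** 2 + lam[1] ** 2 * psi[1], 1e-8, None)
            )
        else:
            delta2 = np.ones(p_ind)
        delta = np.concatenate([np.ones(p_ind), delta2])
        phi = t["phi12"]
        rc = np.array([t[f"rcross[{i}]"] for i in range(p_ind)])
        gam = [np.array([t[f"gamma{w}[{r}]"] for r in range(q)]) for w in (1, 2)]

        def wave(v):
            return 0 if v < p_ind else 1

        def lamv(v):
            return lam[wave(v)][v % p_ind]

        out = []
        for w in (1, 2):
            for i, c in enumerate(item_cats):
                for k in range(c - 1):
                    for cand in (f"tau{w}[{i},{k}]", f"tau[{i},{k}]"):
                        if cand in idx:
                            tv = t[cand]
                            break
                    if w == 2 and step in ("thresholds", "residuals"):
                        tv = delta2[i] * (tv - lam[1][i] * alpha[1])
                    out.append(tv)
        for v in range(p):
            w = wave(v)
            for r in range(q):
                out.append(delta[v] * lamv(v) * gam[w][r])
        for (i, j) in pairs:
            wi, wj = wave(i), wave(j)
            if wi == wj:
                val = lamv(i) * lamv(j) * psi[wi]
            else:
                val = lamv(i) * lamv(j) * phi
                if i % p_ind == j % p_ind:
                    val += rc[i % p_ind]
            out.append(delta[i] * delta[j] * val)
        return np.array(out)

    return sigma, x0, (lo, hi), names


def build_longitudinal_ladder(
    summary_joint: PolychoricSummary,
    *,
    item_cats: tuple[int, ...] = (4, 3, 2, 2),
    q_factor: int = 0,
) -> InvarianceLadder:
    """Four-step ladder over the joint two-wave summary (8 variables)."""
    p_ind = len(item_cats)
    if summary_joint.p != 2 * p_ind:
        raise ValueError("joint summary must stack both waves' items")
    stage1_tau = [summary_joint.thresholds[v] for v in summary_joint.var_names]
    fits = []
    for step in LADDER_STEPS:
        sigma, x0, bounds, names = _longitudinal_model(
            step, item_cats, q_factor, stage1_tau
        )
        df = len(summary_joint.s) - len(names)
        spec = ModelSpec(item_cats=tuple(item_cats) * 2, q_factor=q_factor)
        fits.append(
            fit_generic([summary_joint], spec, sigma, x0, bounds, names, df)
        )
    diffs = [scaled_diff_test(fits[i], fits[i + 1]) for i in range(3)]
    return InvarianceLadder(grouping="wave", steps=list(LADDER_STEPS),
                            fits=fits, diffs=diffs)
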