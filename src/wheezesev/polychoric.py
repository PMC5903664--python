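"""Stage-1 statistics for ordinal-probit factor analysis.

Ordinal items are modelled as coarse measurements of continuous latent
responses y*: item i with c_i categories has c_i - 1 thresholds on the y*
scale, estimated by (ordered) probit regression.  Pairwise associations
between latent responses are polychoric correlations, estimated in a second
stage with the univariate parameters held fixed.  The asymptotic covariance
matrix of the stacked statistics (thresholds, probit slopes, correlations)
is assembled from estimating-equation influence functions in sandwich form;
its diagonal is the weight vector used by the diagonally weighted least
squares fit.

Missing responses use per-item available cases for univariate fits and
pairwise-complete cases for correlations, which operationalises missingness
at random conditional on the probit covariates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from .items import MISSING, DesignMatrix, ItemResponseTable

RHO_CAP = 0.999
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)
_INF = 12.0  # effective infinity on the standard-normal scale


def _phi2(h, k, rho):
    """Standard bivariate normal density, vectorized; 0 at infinite bounds."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    om = 1.0 - rho * rho
    z = (h * h - 2.0 * rho * h * k + k * k) / om
    out = np.exp(-0.5 * z) / (2.0 * np.pi * np.sqrt(om))
    out = np.where((np.abs(h) >= _INF) | (np.abs(k) >= _INF), 0.0, out)
    return out


def bvn_cdf(h, k, rho: float):
    """P(Z1 <= h, Z2 <= k) for standard bivariate normal with correlation rho.

    Uses the correlation-integral identity Phi2(h,k;r) = Phi(h)Phi(k) +
    int_0^r phi2(h,k;t) dt with fixed-order Gauss-Legendre quadrature,
    vectorized over (h, k).
    """
    h = np.atleast_1d(np.asarray(h, dtype=float)).clip(-_INF, _INF)
    k = np.atleast_1d(np.asarray(k, dtype=float)).clip(-_INF, _INF)
    base = ndtr(h) * ndtr(k)
    if rho == 0.0:
        return base
    r = float(np.clip(rho, -RHO_CAP, RHO_CAP))
    t = 0.5 * r * (_GL_NODES + 1.0)  # nodes on [0, r]
    w = 0.5 * r * _GL_WEIGHTS
    acc = _phi2(h[..., None], k[..., None], t) @ w
    out = base + acc
    lo = np.maximum(0.0, ndtr(h) + ndtr(k) - 1.0)
    hi = np.minimum(ndtr(h), ndtr(k))
    return np.clip(out, lo, hi)


# ---------------------------------------------------------------------------
# Univariate ordered probit (stage 1a)
# ---------------------------------------------------------------------------

@dataclass
class UnivariateFit:
    """Thresholds/slopes of one item plus its per-child influence functions."""

    tau: np.ndarray            # c-1 thresholds
    slopes: np.ndarray         # q probit slopes (empty without covariates)
    observed: np.ndarray       # boolean mask of available cases (length n)
    influence: np.ndarray      # n x (c-1+q) influence functions (0 where missing)
    gradient_norm: float
    collapse_map: np.ndarray   # original code -> collapsed code


def _collapse_empty(codes: np.ndarray, n_cats: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Merge categories with zero observed count into a neighbour.

    Boundary empties collapse inward, interior empties into the lower
    neighbour; estimable quantities are unchanged.
    """
    obs = codes[codes != MISSING]
    counts = np.bincount(obs, minlength=n_cats)
    cmap = np.zeros(n_cats, dtype=np.int64)
    nxt = 0
    for k in range(n_cats):
        if counts[k] == 0:
            cmap[k] = max(nxt - 1, 0)
        else:
            cmap[k] = nxt
            nxt += 1
    if nxt < 2:
        raise ValueError("item has fewer than 2 observed categories")
    # leading empty categories map to 0 already via max(.,0)
    out = codes.copy()
    m = out != MISSING
    out[m] = cmap[out[m]]
    return out, cmap, nxt


def univariate_probit(
    item: np.ndarray,
    X: np.ndarray | None = None,
    n_cats: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Thresholds (and slopes, given covariates) of one ordinal item.

    Without covariates the thresholds are the inverse-normal transforms of
    the cumulative observed proportions; with covariates they come from an
    ordered-probit maximum-likelihood fit with unit residual variance.
    """
    fit = _fit_univariate(item, X, n_cats)
    return fit.tau, fit.slopes


def _fit_univariate(
    item: np.ndarray,
    X: np.ndarray | None = None,
    n_cats: int | None = None,
) -> UnivariateFit:
    codes = np.asarray(item, dtype=np.int64)
    if n_cats is None:
        n_cats = int(codes[codes != MISSING].max()) + 1
    codes, cmap, c = _collapse_empty(codes, n_cats)
    n = len(codes)
    obs = codes != MISSING
    m = int(obs.sum())
    if X is None or X.shape[1] == 0:
        counts = np.bincount(codes[obs], minlength=c)
        F = np.cumsum(counts)[:-1] / m
        tau = ndtri(F)
        phi = norm.pdf(tau)
        infl = np.zeros((n, c - 1))
        yk = codes[obs, None] <= np.arange(c - 1)[None, :]
        infl[obs] = (yk - F[None, :]) / (m * phi[None, :])
        return UnivariateFit(tau, np.zeros(0), obs, infl, 0.0, cmap)

    Xo = np.asarray(X, dtype=float)[obs]
    y = codes[obs]
    q = Xo.shape[1]
    counts = np.bincount(y, minlength=c)
    tau0 = ndtri(np.cumsum(counts)[:-1] / m)

    def unpack(z):
        tau = np.empty(c - 1)
        tau[0] = z[0]
        if c > 2:
            tau[1:] = z[0] + np.cumsum(np.exp(z[1 : c - 1]))
        return tau, z[c - 1 :]

    def cell_bounds(tau, b):
        xb = Xo @ b
        hi = np.where(y == c - 1, _INF, tau[np.minimum(y, c - 2)]) - xb
        lo = np.where(y == 0, -_INF, tau[np.maximum(y - 1, 0)]) - xb
        return lo, hi

    def negll_grad(z):
        tau, b = unpack(z)
        lo, hi = cell_bounds(tau, b)
        P = np.clip(ndtr(hi) - ndtr(lo), 1e-300, None)
        ll = np.log(P).sum()
        dhi = norm.pdf(hi) / P
        dlo = -norm.pdf(lo) / P
        # gradient wrt tau: dhi adds to tau[y] (y<c-1), dlo to tau[y-1] (y>0)
        gtau = np.zeros(c - 1)
        np.add.at(gtau, np.minimum(y, c - 2), np.where(y < c - 1, dhi, 0.0))
        np.add.at(gtau, np.maximum(y - 1, 0), np.where(y > 0, dlo, 0.0))
        gb = -((dhi + dlo)[:, None] * Xo).sum(axis=0)
        # chain rule to unconstrained z
        gz = np.empty_like(z)
        gz[0] = gtau.sum()
        for j in range(1, c - 1):
            gz[j] = gtau[j:].sum() * np.exp(z[j])
        gz[c - 1 :] = gb
        return -ll, -gz

    z0 = np.concatenate(
        [[tau0[0]], np.log(np.clip(np.diff(tau0), 1e-3, None)), np.zeros(q)]
    )
    res = minimize(negll_grad, z0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10})
    tau, b = unpack(res.x)
    # per-observation scores in the (tau, b) parameterization
    lo, hi = cell_bounds(tau, b)
    P = np.clip(ndtr(hi) - ndtr(lo), 1e-300, None)
    dhi = norm.pdf(hi) / P
    dlo = -norm.pdf(lo) / P
    G = np.zeros((int(obs.sum()), c - 1 + q))
    rows = np.arange(len(y))
    up = y < c - 1
    G[rows[up], np.minimum(y, c - 2)[up]] = dhi[up]
    low = y > 0
    G[rows[low], np.maximum(y - 1, 0)[low]] += dlo[low]
    G[:, c - 1 :] = -(dhi + dlo)[:, None] * Xo
    gnorm = float(np.linalg.norm(G.sum(axis=0)))
    if gnorm > 1e-4 * m:
        raise RuntimeError(
            f"ordered probit did not converge (gradient norm {gnorm:.3g})"
        )
    A = G.T @ G  # outer-product information of the summed score
    try:
        infl_obs = np.linalg.solve(A, G.T).T
    except np.linalg.LinAlgError as e:
        raise RuntimeError(
            "singular information matrix; possible complete separation "
            f"(covariate column condition: {np.linalg.cond(Xo):.2g})"
        ) from e
    infl = np.zeros((n, c - 1 + q))
    infl[obs] = infl_obs
    return UnivariateFit(tau, b, obs, infl, gnorm, cmap)


# ---------------------------------------------------------------------------
# Pairwise polychoric correlation (stage 1b)
# ---------------------------------------------------------------------------

def _pair_cells(ci, cj, tau_i, tau_j, xb_i, xb_j, yi, yj):
    """Collapse pairwise-complete observations into unique (bounds, count) cells."""
    # bounds per observation
    ti = np.concatenate([[-_INF], tau_i, [_INF]])
    tj = np.concatenate([[-_INF], tau_j, [_INF]])
    Ui = ti[yi + 1] - xb_i
    Li = ti[yi] - xb_i
    Uj = tj[yj + 1] - xb_j
    Lj = tj[yj] - xb_j
    B = np.column_stack([Ui, Li, Uj, Lj])
    uniq, inverse, counts = np.unique(
        B.round(12), axis=0, return_inverse=True, return_counts=True
    )
    return uniq, inverse, counts


def _cell_probs(uniq, rho):
    Ui, Li, Uj, Lj = uniq.T
    P = (
        bvn_cdf(Ui, Uj, rho)
        - bvn_cdf(Li, Uj, rho)
        - bvn_cdf(Ui, Lj, rho)
        + bvn_cdf(Li, Lj, rho)
    )
    return np.clip(P, 1e-300, None)


def polychoric_pair(
    item_i: np.ndarray,
    item_j: np.ndarray,
    X: np.ndarray | None = None,
    tau_i: np.ndarray | None = None,
    tau_j: np.ndarray | None = None,
    slopes_i: np.ndarray | None = None,
    slopes_j: np.ndarray | None = None,
) -> float:
    """Polychoric (tetrachoric for binary pairs) correlation of two items.

    Thresholds/slopes are held fixed at their stage-1 values (two-stage
    estimation); only the correlation is profiled, by bounded 1-D
    minimization of the bivariate-normal likelihood of the cross-table.
    """
    yi = np.asarray(item_i, dtype=np.int64)
    yj = np.asarray(item_j, dtype=np.int64)
    # canonical argument order makes the estimate exactly symmetric
    if (yi.tobytes(), b"" if tau_i is None else np.asarray(tau_i).tobytes()) > (
        yj.tobytes(), b"" if tau_j is None else np.asarray(tau_j).tobytes()
    ):
        yi, yj = yj, yi
        tau_i, tau_j = tau_j, tau_i
        slopes_i, slopes_j = slopes_j, slopes_i
    both = (yi != MISSING) & (yj != MISSING)
    if both.sum() < 10:
        raise ValueError("fewer than 10 pairwise-complete observations")
    if tau_i is None:
        fi = _fit_univariate(yi, X)
        tau_i, slopes_i = fi.tau, fi.slopes
        yi = yi.copy()
        m = yi != MISSING
        yi[m] = fi.collapse_map[yi[m]]
    if tau_j is None:
        fj = _fit_univariate(yj, X)
        tau_j, slopes_j = fj.tau, fj.slopes
        yj = yj.copy()
        m = yj != MISSING
        yj[m] = fj.collapse_map[yj[m]]
    if X is None or slopes_i is None or slopes_i.size == 0:
        xb_i = np.zeros(int(both.sum()))
        xb_j = np.zeros(int(both.sum()))
    else:
        xb_i = X[both] @ slopes_i
        xb_j = X[both] @ slopes_j
    uniq, _, counts = _pair_cells(
        len(tau_i) + 1, len(tau_j) + 1, tau_i, tau_j, xb_i, xb_j, yi[both], yj[both]
    )

    def nll(r):
        return -(counts * np.log(_cell_probs(uniq, r))).sum()

    res = minimize_scalar(nll, bounds=(-RHO_CAP, RHO_CAP), method="bounded",
                          options={"xatol": 1e-10})
    rho = float(res.x)
    if abs(rho) >= RHO_CAP - 1e-6:
        warnings.warn("polychoric correlation at cap; degenerate cross-table")
    return rho


def _pair_scores(uniq, rho):
    """Per-cell d log P / d rho and dP/d(bounds) for the influence machinery."""
    Ui, Li, Uj, Lj = uniq.T
    P = _cell_probs(uniq, rho)
    dP_rho = (
        _phi2(Ui, Uj, rho) - _phi2(Li, Uj, rho)
        - _phi2(Ui, Lj, rho) + _phi2(Li, Lj, rho)
    )
    t = np.sqrt(1.0 - rho * rho)

    def dPhi2_dh(h, k):
        with np.errstate(invalid="ignore"):
            val = norm.pdf(h) * ndtr((k - rho * h) / t)
        return np.where(np.abs(h) >= _INF, 0.0, val)

    dP_Ui = dPhi2_dh(Ui, Uj) - dPhi2_dh(Ui, Lj)
    dP_Li = -(dPhi2_dh(Li, Uj) - dPhi2_dh(Li, Lj))
    dP_Uj = dPhi2_dh(Uj, Ui) - dPhi2_dh(Uj, Li)
    dP_Lj = -(dPhi2_dh(Lj, Ui) - dPhi2_dh(Lj, Li))
    return P, dP_rho, (dP_Ui, dP_Li, dP_Uj, dP_Lj)


# ---------------------------------------------------------------------------
# Summary assembly
# ---------------------------------------------------------------------------

@dataclass
class PolychoricSummary:
    """Stacked stage-1 statistics with sandwich asymptotic covariance.

    Statistic order: all thresholds variable by variable, then probit slopes
    variable-major, then polychoric correlations for pairs (i, j), i < j, in
    row-major order.  ``gamma`` is the covariance matrix of the statistic
    vector as an estimate (already scaled by sample size); ``w_diag`` is its
    diagonal, the DWLS weight vector.
    """

    var_names: list[str]
    n_cats: list[int]
    x_names: list[str]
    thresholds: dict[str, np.ndarray]
    slopes: dict[str, np.ndarray]
    R: np.ndarray
    stat_names: list[str]
    s: np.ndarray
    gamma: np.ndarray
    w_diag: np.ndarray
    n: int
    n_per_stat: np.ndarray
    influence: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return len(self.var_names)

    @property
    def q(self) -> int:
        return len(self.x_names)

    def stat_slices(self) -> dict[str, slice]:
        """Slices of the threshold, slope and correlation blocks."""
        n_tau = sum(c - 1 for c in self.n_cats)
        n_slope = self.p * self.q
        return {
            "tau": slice(0, n_tau),
            "slope": slice(n_tau, n_tau + n_slope),
            "rho": slice(n_tau + n_slope, len(self.s)),
        }

    # -- serialization (sufficient-statistics bundle) ----------------------

    def to_dir(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "var_names": self.var_names,
            "n_cats": self.n_cats,
            "x_names": self.x_names,
            "stat_names": self.stat_names,
            "n": self.n,
            "n_per_stat": self.n_per_stat.tolist(),
            "thresholds": {k: v.tolist() for k, v in self.thresholds.items()},
            "slopes": {k: v.tolist() for k, v in self.slopes.items()},
        }
        (path / "summary.json").write_text(json.dumps(meta, indent=1))
        np.savetxt(path / "s.tsv", self.s, delimiter="\t")
        np.savetxt(path / "gamma.tsv", self.gamma, delimiter="\t")
        np.savetxt(path / "R.tsv", self.R, delimiter="\t")
        return path

    @classmethod
    def from_dir(cls, path: str | Path) -> "PolychoricSummary":
        path = Path(path)
        meta = json.loads((path / "summary.json").read_text())
        s = np.atleast_1d(np.loadtxt(path / "s.tsv"))
        gamma = np.atleast_2d(np.loadtxt(path / "gamma.tsv"))
        R = np.atleast_2d(np.loadtxt(path / "R.tsv"))
        return cls(
            var_names=meta["var_names"],
            n_cats=meta["n_cats"],
            x_names=meta["x_names"],
            thresholds={k: np.array(v) for k, v in meta["thresholds"].items()},
            slopes={k: np.array(v) for k, v in meta["slopes"].items()},
            R=R,
            stat_names=meta["stat_names"],
            s=s,
            gamma=gamma,
            w_diag=np.diag(gamma).copy(),
            n=meta["n"],
            n_per_stat=np.array(meta["n_per_stat"]),
        )


def assemble_summary(
    table: ItemResponseTable,
    X: DesignMatrix | np.ndarray | None = None,
    variables: Sequence[str] | None = None,
    *,
    x_names: Sequence[str] | None = None,
    keep_influence: bool = True,
    listwise: bool = False,
) -> PolychoricSummary:
    """Estimate all stage-1 statistics and their asymptotic covariance.

    The overall ``n`` reported for fit statistics is the number of children
    with at least one observed indicator.  ``listwise=True`` restricts every
    statistic to complete cases (sensitivity option; pairwise is default).
    """
    if isinstance(X, DesignMatrix):
        x_names = list(X.names)
        Xmat = X.X
    elif X is not None:
        Xmat = np.asarray(X, dtype=float)
        x_names = list(x_names) if x_names is not None else [
            f"x{j}" for j in range(Xmat.shape[1])
        ]
    else:
        Xmat = None
        x_names = []

    names = list(variables) if variables is not None else table.item_names
    p = len(names)
    Y = np.column_stack([np.asarray(table.codes[v], dtype=np.int64) for v in names])
    if listwise:
        keep = (Y != MISSING).all(axis=1)
        Y = np.where(keep[:, None], Y, MISSING)
    n = Y.shape[0]

    fits: list[UnivariateFit] = []
    n_cats: list[int] = []
    for j, v in enumerate(names):
        c_declared = table.specs[v].n_categories
        fit = _fit_univariate(Y[:, j], Xmat, c_declared)
        # apply collapse map so pair stage sees collapsed codes
        m = Y[:, j] != MISSING
        Y[m, j] = fit.collapse_map[Y[m, j]]
        fits.append(fit)
        n_cats.append(len(fit.tau) + 1)

    q = len(x_names)
    stat_names: list[str] = []
    for v, f in zip(names, fits):
        stat_names += [f"tau[{v},{k+1}]" for k in range(len(f.tau))]
    for v in names:
        stat_names += [f"slope[{v},{x}]" for x in x_names]
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    stat_names += [f"rho[{names[i]},{names[j]}]" for i, j in pairs]
    dim = len(stat_names)

    IF = np.zeros((n, dim))
    s = np.zeros(dim)
    n_per = np.zeros(dim)
    # threshold & slope blocks
    tau_off: dict[int, int] = {}
    off = 0
    for j, f in enumerate(fits):
        k = len(f.tau)
        tau_off[j] = off
        s[off : off + k] = f.tau
        IF[:, off : off + k] = f.influence[:, :k]
        n_per[off : off + k] = f.observed.sum()
        off += k
    n_tau = off
    slope_off: dict[int, int] = {}
    for j, f in enumerate(fits):
        slope_off[j] = off
        if q:
            s[off : off + q] = f.slopes
            IF[:, off : off + q] = f.influence[:, len(f.tau) :]
            n_per[off : off + q] = f.observed.sum()
            off += q

    R = np.eye(p)
    for idx, (i, j) in enumerate(pairs):
        pos = n_tau + p * q + idx
        fi, fj = fits[i], fits[j]
        both = fi.observed & fj.observed
        m = int(both.sum())
        if m < 10:
            raise ValueError(f"pair ({names[i]},{names[j]}): too few complete cases")
        if Xmat is None or q == 0:
            xb_i = np.zeros(m)
            xb_j = np.zeros(m)
        else:
            xb_i = Xmat[both] @ fi.slopes
            xb_j = Xmat[both] @ fj.slopes
        yi, yj = Y[both, i], Y[both, j]
        uniq, inverse, counts = _pair_cells(
            n_cats[i], n_cats[j], fi.tau, fj.tau, xb_i, xb_j, yi, yj
        )

        def nll(r, uniq=uniq, counts=counts):
            return -(counts * np.log(_cell_probs(uniq, r))).sum()

        res = minimize_scalar(nll, bounds=(-RHO_CAP, RHO_CAP), method="bounded",
                              options={"xatol": 1e-10})
        rho = float(res.x)
        R[i, j] = R[j, i] = rho
        s[pos] = rho
        n_per[pos] = m

        # influence functions for rho (two-stage corrected)
        P, dP_rho, (dU_i, dL_i, dU_j, dL_j) = _pair_scores(uniq, rho)
        v_cell = dP_rho / P  # score wrt rho per cell
        v_obs = v_cell[inverse]
        # bivariate score wrt item thresholds/slopes, per cell, mapped per obs
        ci, cj = n_cats[i], n_cats[j]
        cols_i = list(range(tau_off[i], tau_off[i] + ci - 1))
        cols_j = list(range(tau_off[j], tau_off[j] + cj - 1))
        if q:
            cols_i += list(range(slope_off[i], slope_off[i] + q))
            cols_j += list(range(slope_off[j], slope_off[j] + q))
        S_tau = np.zeros((m, len(cols_i) + len(cols_j)))
        rows = np.arange(m)
        up_i = yi < ci - 1
        S_tau[rows[up_i], yi[up_i]] = (dU_i / P)[inverse][up_i]
        lo_i = yi > 0
        np.add.at(S_tau, (rows[lo_i], yi[lo_i] - 1), (dL_i / P)[inverse][lo_i])
        base_j = ci - 1 + (q if q else 0)
        up_j = yj < cj - 1
        S_tau[rows[up_j], base_j + yj[up_j]] = (dU_j / P)[inverse][up_j]
        lo_j = yj > 0
        np.add.at(S_tau, (rows[lo_j], base_j + yj[lo_j] - 1), (dL_j / P)[inverse][lo_j])
        if q:
            dsum_i = ((dU_i + dL_i) / P)[inverse]
            dsum_j = ((dU_j + dL_j) / P)[inverse]
            S_tau[:, ci - 1 : ci - 1 + q] = -dsum_i[:, None] * Xmat[both]
            S_tau[:, base_j + cj - 1 :] = -dsum_j[:, None] * Xmat[both]
        H_rho = float(v_obs @ v_obs)
        C = -(v_obs @ S_tau)  # d(sum score_rho)/d(theta_uni), info identity
        if_tau_cols = IF[:, cols_i + cols_j]
        contrib = np.zeros(n)
        contrib[both] = v_obs
        IF[:, pos] = (contrib + if_tau_cols @ C) / H_rho

    gamma = IF.T @ IF
    gamma = 0.5 * (gamma + gamma.T)
    w = np.diag(gamma).copy()
    if (w <= 0).any():
        raise ValueError("non-positive weight diagonal; summary not usable")
    eigmin = float(np.linalg.eigvalsh(gamma).min())
    if eigmin < -1e-8 * float(np.abs(gamma).max()):
        raise ValueError(
            f"asymptotic covariance not PSD (min eigenvalue {eigmin:.3g}, "
            f"condition number {np.linalg.cond(gamma):.3g})"
        )

    n_overall = int(((Y != MISSING).any(axis=1)).sum())
    return PolychoricSummary(
        var_names=names,
        n_cats=n_cats,
        x_names=list(x_names),
        thresholds={v: f.tau for v, f in zip(names, fits)},
        slopes={v: f.slopes for v, f in zip(names, fits)},
        R=R,
        stat_names=stat_names,
        s=s,
        gamma=gamma,
        w_diag=w,
        n=n_overall,
        n_per_stat=n_per,
        influence=IF if keep_influence else None,
    )


def cluster_robust_gamma(
    summary: PolychoricSummary, cluster_ids: np.ndarray
) -> np.ndarray:
    """Cluster-robust asymptotic covariance: influence functions are summed
    within cluster before the outer-product aggregation."""
    if summary.influence is None:
        raise ValueError("summary was built without influence functions")
    ids = np.asarray(cluster_ids)
    if len(ids) != summary.influence.shape[0]:
        raise ValueError("cluster ids inconsistent with influence rows")
    uniq, inv = np.unique(ids, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    G = np.zeros((len(uniq), summary.influence.shape[1]))
    np.add.at(G, inv, summary.influence)
    gamma = G.T @ G
    return 0.5 * (gamma + gamma.T)
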