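"""Normal-ogive graded response model: marginal ML, EAP scores, information.

The probit graded response model is an exact reparameterization of the
delta-parameterized one-factor ordinal CFA: discrimination
a_i = lambda_i / sqrt(1 - lambda_i^2) and category boundaries
b_ik = tau_ik / lambda_i.  Fitting it by marginal maximum likelihood (EM
over Gauss-Hermite quadrature) therefore provides an estimator of the same
measurement model that shares nothing with the weighted least squares
route -- the cross-check used to validate both.

Expected-a-posteriori (EAP) severity scores and Fisher information curves
summarize where on the severity continuum the four items measure well;
missing responses simply contribute no likelihood term (missing at random).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import norm

from .items import MISSING, ItemResponseTable

A_MAX = 10.0


@dataclass
class GrmParams:
    """Per-item discrimination and ordered category boundaries."""

    names: list[str]
    a: np.ndarray                 # discriminations, > 0
    b: list[np.ndarray]           # boundaries, strictly increasing
    loglik: float = np.nan
    n_iter: int = 0

    def __post_init__(self) -> None:
        if (self.a <= 0).any():
            raise ValueError("discriminations must be positive")
        for bb in self.b:
            if (np.diff(bb) <= 0).any():
                raise ValueError("category boundaries must be increasing")

    @classmethod
    def from_cfa(cls, names, loadings, thresholds) -> "GrmParams":
        lam = np.asarray(loadings, dtype=float)
        a = lam / np.sqrt(1.0 - lam**2)
        b = [np.asarray(t, dtype=float) / l for t, l in zip(thresholds, lam)]
        return cls(list(names), a, b)

    def to_cfa(self) -> tuple[np.ndarray, list[np.ndarray]]:
        lam = self.a / np.sqrt(1.0 + self.a**2)
        tau = [bb * l for bb, l in zip(self.b, lam)]
        return lam, tau


def _ghe_quadrature(k: int):
    """Gauss-Hermite nodes/weights for a standard normal integrand."""
    x, w = np.polynomial.hermite.hermgauss(k)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


def _cat_probs(a: float, b: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """len(grid) x c matrix of category probabilities at each ability."""
    ge = ndtr(a * (grid[:, None] - b[None, :]))  # P(y >= k+1)
    upper = np.hstack([np.ones((len(grid), 1)), ge])
    lower = np.hstack([ge, np.zeros((len(grid), 1))])
    return np.clip(upper - lower, 1e-300, None)


def _patterns(Y: np.ndarray):
    uniq, inverse, counts = np.unique(Y, axis=0, return_inverse=True,
                                      return_counts=True)
    return uniq, inverse, counts


def fit_grm(
    table: ItemResponseTable,
    n_quadrature: int = 61,
    *,
    items: list[str] | None = None,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> GrmParams:
    """Marginal maximum likelihood by EM over Gauss-Hermite quadrature.

    The marginal log-likelihood is non-decreasing across EM iterations;
    discriminations escaping to the boundary are capped at 10 with a
    warning.
    """
    if n_quadrature < 21:
        raise ValueError("use at least 21 quadrature nodes")
    names = items if items is not None else table.item_names
    if len(names) < 2:
        raise ValueError("graded response fit needs >= 2 items")
    Y = table.item_matrix(names)
    n_cats = [table.specs[v].n_categories for v in names]
    grid, wq = _ghe_quadrature(n_quadrature)
    uniq, _, counts = _patterns(Y)
    R, p = uniq.shape

    # starting values from univariate margins at a moderate loading
    lam0 = 0.7
    a = np.full(p, lam0 / np.sqrt(1 - lam0**2))
    b = []
    for j, c in enumerate(n_cats):
        obs = Y[:, j][Y[:, j] != MISSING]
        cnt = np.bincount(obs, minlength=c).astype(float)
        cum = np.clip(np.cumsum(cnt)[:-1] / cnt.sum(), 1e-4, 1 - 1e-4)
        b.append(norm.ppf(cum) / lam0)

    def pattern_loglik():
        L = np.ones((R, len(grid)))
        for j in range(p):
            P = _cat_probs(a[j], b[j], grid)  # Q x c
            obs = uniq[:, j]
            m = obs != MISSING
            L[m] *= P[:, obs[m]].T
        marg = L @ wq
        return L, marg, float(counts @ np.log(np.clip(marg, 1e-300, None)))

    prev_ll = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        L, marg, ll = pattern_loglik()
        if ll + 1e-9 < prev_ll:
            warnings.warn("EM log-likelihood decreased; stopping")
            break
        if abs(ll - prev_ll) < tol:
            prev_ll = ll
            break
        prev_ll = ll
        # posterior weight of node q for pattern r, times pattern count
        W = (L * wq[None, :]) / marg[:, None] * counts[:, None]  # R x Q
        for j in range(p):
            obs = uniq[:, j]
            m = obs != MISSING
            if not m.any():
                continue
            # expected count of (node, category) for item j
            Nqc = np.zeros((len(grid), n_cats[j]))
            for k in range(n_cats[j]):
                rows = m & (obs == k)
                if rows.any():
                    Nqc[:, k] = W[rows].sum(axis=0)
            cj = n_cats[j]

            def unpack(z):
                aj = z[0]
                bj = np.empty(cj - 1)
                bj[0] = z[1]
                if cj > 2:
                    bj[1:] = z[1] + np.cumsum(np.exp(z[2:]))
                return aj, bj

            def negq(z):
                aj, bj = unpack(z)
                P = _cat_probs(aj, bj, grid)
                return -(Nqc * np.log(P)).sum()

            z0 = np.concatenate(
                [[a[j]], [b[j][0]], np.log(np.clip(np.diff(b[j]), 1e-4, None))]
            )
            res = minimize(negq, z0, method="L-BFGS-B",
                           bounds=[(1e-3, A_MAX)] + [(None, None)] * (cj - 1),
                           options={"maxiter": 200, "ftol": 1e-12})
            a[j], b[j] = unpack(res.x)
    else:
        raise RuntimeError(f"EM did not converge in {max_iter} iterations")
    if (a >= A_MAX - 1e-6).any():
        warnings.warn("discrimination capped at 10")
    return GrmParams(list(names), a.copy(), [bb.copy() for bb in b],
                     loglik=prev_ll, n_iter=it)


@dataclass
class EapScore:
    mean: np.ndarray
    sd: np.ndarray
    all_missing: np.ndarray  # flags: prior returned


def eap_score(
    params: GrmParams, responses: np.ndarray, n_quadrature: int = 61
) -> EapScore:
    """Posterior mean/SD of severity under a standard-normal prior."""
    Y = np.atleast_2d(np.asarray(responses, dtype=np.int64))
    grid, wq = _ghe_quadrature(n_quadrature)
    uniq, inverse, _ = _patterns(Y)
    L = np.ones((len(uniq), len(grid)))
    for j in range(len(params.a)):
        P = _cat_probs(params.a[j], params.b[j], grid)
        obs = uniq[:, j]
        m = obs != MISSING
        L[m] *= P[:, obs[m]].T
    post = L * wq[None, :]
    norm_c = post.sum(axis=1, keepdims=True)
    post = post / norm_c
    mean_u = post @ grid
    var_u = post @ grid**2 - mean_u**2
    allmiss_u = (uniq == MISSING).all(axis=1)
    return EapScore(
        mean=mean_u[inverse],
        sd=np.sqrt(np.clip(var_u, 1e-12, None))[inverse],
        all_missing=allmiss_u[inverse],
    )


@dataclass
class InformationCurve:
    grid: np.ndarray
    per_item: np.ndarray  # p x len(grid)
    total: np.ndarray

    def peak(self) -> float:
        return float(self.grid[np.argmax(self.total)])


def item_information(params: GrmParams, grid: np.ndarray) -> InformationCurve:
    """Fisher information of each item's categorical likelihood.

    I_i(eta) = sum_k (dP_k/deta)^2 / P_k; the total curve is the sum over
    items, highest where the item thresholds concentrate.
    """
    grid = np.asarray(grid, dtype=float)
    p = len(params.a)
    info = np.zeros((p, len(grid)))
    for j in range(p):
        a, b = params.a[j], params.b[j]
        P = _cat_probs(a, b, grid)
        ge = a * norm.pdf(a * (grid[:, None] - b[None, :]))  # d P(y>=k+1) / deta
        upper = np.hstack([np.zeros((len(grid), 1)), ge])
        lower = np.hstack([ge, np.zeros((len(grid), 1))])
        dP = upper - lower
        info[j] = ((dP**2) / P).sum(axis=1)
    return InformationCurve(grid=grid, per_item=info, total=info.sum(axis=0))
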