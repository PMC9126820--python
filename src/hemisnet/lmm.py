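"""Random-intercept linear mixed model, profiled REML.

The case-control models all share one structure: a continuous outcome,
a small fixed-effects design (diagnosis, age, sex, optional extras) and
a single random intercept per dataset. For that structure the REML
criterion can be profiled down to a one-dimensional search over the
variance ratio ``lambda = tau^2 / sigma^2`` using only per-dataset sums
(Woodbury identity on the block-of-ones random-effects covariance),
which makes a fit cheap enough to repeat for every label-swap
permutation. The same estimator is used for observed and permuted fits,
so the permutation test is valid by exchangeability regardless of the
estimator's finite-sample behaviour.

The batched path (`batched_diagnosis_t`) refits the model for thousands
of permuted diagnosis columns simultaneously: a coarse common grid over
``lambda`` followed by a vectorized golden-section refinement, with all
per-permutation quantities assembled from group sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0
_LAMBDA_GRID = np.concatenate([[0.0], np.logspace(-6.0, 4.0, 41)])
_RSS_FLOOR = 1e-28


class SingularFitError(ValueError):
    """The fixed-effects design is singular for this outcome/grouping."""


@dataclass
class LMMFit:
    """REML fit summary; ``beta[0]`` is always the diagnosis-like column."""

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    df: int
    lambda_hat: float
    sigma2: float
    tau2: float


class _Precomputed:
    """Sufficient statistics for the profiled criterion.

    ``d_cols`` holds B versions of the focal (diagnosis) column; all
    other design columns ``F`` are shared across the batch.
    """

    def __init__(self, F: np.ndarray, d_cols: np.ndarray, y: np.ndarray, groups: np.ndarray):
        F = np.asarray(F, dtype=float)
        d_cols = np.asarray(d_cols, dtype=float)
        if d_cols.ndim == 1:
            d_cols = d_cols[:, None]
        y = np.asarray(y, dtype=float)
        codes, counts = _group_codes(groups)
        n, p1 = F.shape
        G = len(counts)
        if G < 2:
            raise ValueError("need >= 2 datasets for a random-intercept model")
        if np.ptp(y) == 0:
            raise ValueError("outcome is constant; model cannot be fit")

        self.n, self.p = n, p1 + 1
        self.n_g = counts.astype(float)
        self.FtF = F.T @ F
        self.FtD = F.T @ d_cols  # (p1, B)
        self.dtd = np.einsum("nb,nb->b", d_cols, d_cols)
        self.Fty = F.T @ y
        self.Dty = d_cols.T @ y
        self.yty = float(y @ y)
        self.S_F = np.zeros((G, p1))
        np.add.at(self.S_F, codes, F)
        self.S_D = np.zeros((G, d_cols.shape[1]))
        np.add.at(self.S_D, codes, d_cols)
        self.t_g = np.bincount(codes, weights=y, minlength=G)
        self.B = d_cols.shape[1]

    def assemble(self, lam: np.ndarray):
        """A = X'V0^-1 X, c = X'V0^-1 y, q = y'V0^-1 y for per-batch lambda."""
        lam = np.asarray(lam, dtype=float)
        theta = lam[None, :] / (1.0 + lam[None, :] * self.n_g[:, None])  # (G, B)
        tSD = theta * self.S_D
        A = np.empty((self.B, self.p, self.p))
        A[:, 0, 0] = self.dtd - (tSD * self.S_D).sum(axis=0)
        A1F = self.FtD.T - np.einsum("gb,gi->bi", tSD, self.S_F)
        A[:, 0, 1:] = A1F
        A[:, 1:, 0] = A1F
        A[:, 1:, 1:] = self.FtF[None] - np.einsum("gb,gi,gj->bij", theta, self.S_F, self.S_F)
        c = np.empty((self.B, self.p))
        c[:, 0] = self.Dty - (tSD * self.t_g[:, None]).sum(axis=0)
        c[:, 1:] = self.Fty[None] - np.einsum("gb,g,gi->bi", theta, self.t_g, self.S_F)
        q = self.yty - (theta * (self.t_g**2)[:, None]).sum(axis=0)
        logdet_v0 = np.log1p(lam[None, :] * self.n_g[:, None]).sum(axis=0)
        return A, c, q, logdet_v0

    def criterion(self, lam: np.ndarray) -> np.ndarray:
        """-2 profiled REML log-likelihood, up to an additive constant."""
        A, c, q, logdet_v0 = self.assemble(lam)
        sign, logdet_a = np.linalg.slogdet(A)
        crit = np.full(self.B, np.inf)
        ok = sign > 0
        if ok.any():
            beta = np.linalg.solve(A[ok], c[ok][..., None])[..., 0]
            rss = np.maximum(q[ok] - np.einsum("bp,bp->b", beta, c[ok]), _RSS_FLOOR)
            crit[ok] = (self.n - self.p) * np.log(rss) + logdet_v0[ok] + logdet_a[ok]
        return crit


def _group_codes(groups) -> tuple[np.ndarray, np.ndarray]:
    _, codes = np.unique(np.asarray(groups), return_inverse=True)
    counts = np.bincount(codes)
    return codes, counts


def _optimize_lambda(pre: _Precomputed, n_refine: int = 40) -> np.ndarray:
    crits = np.stack([pre.criterion(np.full(pre.B, lam)) for lam in _LAMBDA_GRID])
    if not np.isfinite(crits).any(axis=0).all():
        raise SingularFitError(
            "singular mixed-model fit (criterion undefined at every "
            "variance ratio); check for unreplicated datasets or a "
            "collinear design"
        )
    best = np.argmin(crits, axis=0)
    a = _LAMBDA_GRID[np.maximum(best - 1, 0)]
    b = _LAMBDA_GRID[np.minimum(best + 1, len(_LAMBDA_GRID) - 1)]
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    for _ in range(n_refine):
        fc = pre.criterion(c)
        fd = pre.criterion(d)
        left = fc < fd
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        c = b - _GOLDEN * (b - a)
        d = a + _GOLDEN * (b - a)
    return (a + b) / 2.0


def _solve_fit(pre: _Precomputed, lam: np.ndarray):
    A, c, q, _ = pre.assemble(lam)
    sign, _ = np.linalg.slogdet(A)
    if (sign <= 0).any():
        raise SingularFitError("singular fixed-effects design in mixed-model fit")
    beta = np.linalg.solve(A, c[..., None])[..., 0]
    rss = np.maximum(q - np.einsum("bp,bp->b", beta, c), _RSS_FLOOR)
    df = pre.n - pre.p
    sigma2 = rss / df
    a_inv = np.linalg.inv(A)
    var_beta = sigma2[:, None] * np.einsum("bpp->bp", a_inv)
    se = np.sqrt(np.maximum(var_beta, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    return beta, se, t, df, sigma2


def fit_random_intercept(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray
) -> LMMFit:
    """REML fit of ``y = X beta + (1 | group) + noise``.

    Column 0 of ``X`` is treated as the focal predictor (its t-statistic
    is the one permutation inference uses); the remaining columns are
    covariates, normally including an intercept.
    """
    X = np.asarray(X, dtype=float)
    pre = _Precomputed(X[:, 1:], X[:, :1], y, groups)
    lam = _optimize_lambda(pre)
    beta, se, t, df, sigma2 = _solve_fit(pre, lam)
    return LMMFit(
        beta=beta[0],
        se=se[0],
        t=t[0],
        df=df,
        lambda_hat=float(lam[0]),
        sigma2=float(sigma2[0]),
        tau2=float(lam[0] * sigma2[0]),
    )


def batched_diagnosis_t(
    F: np.ndarray, d_cols: np.ndarray, y: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    """t-statistics of the focal column for B candidate columns at once.

    ``F`` is the shared covariate design (with intercept); ``d_cols`` is
    (n, B), one permuted diagnosis indicator per column. Each column is
    refit with its own REML variance ratio.
    """
    pre = _Precomputed(F, d_cols, y, groups)
    lam = _optimize_lambda(pre)
    _, _, t, _, _ = _solve_fit(pre, lam)
    return t[:, 0]
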