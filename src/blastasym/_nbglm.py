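"""Vectorized maximum-likelihood fitting of per-gene NB2 log-linear models.

Every hypothesis in the axis tests is an NB2 GLM with a log link, a fixed
log-library-size offset and a small design matrix shared by all genes:

    r_gj ~ NB(mu_gj, alpha_g),   Var = mu + alpha mu^2,
    log mu_gj = log s_j + x_j' beta_g.

Fits are computed jointly for all genes at once.  For a fixed dispersion the
regression coefficients are obtained by iteratively reweighted least squares
(batched across genes); the dispersion is then profiled out on the log scale
by a coarse grid followed by golden-section refinement of each gene's
bracketing interval.  The Poisson limit (alpha -> 0) is always evaluated
explicitly and wins ties, so zero-variance genes land exactly on the
boundary.  Everything is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

ALPHA_MAX = 1e4
#: below this dispersion the Poisson limit of the likelihood is used
ALPHA_POISSON = 1e-8

_LOG_ALPHA_LO = np.log(1e-6)
_LOG_ALPHA_HI = np.log(ALPHA_MAX)
_N_GRID = 28
_GOLDEN_ITERS = 34
_IRLS_MAX = 60
_IRLS_TOL = 1e-12
_ETA_CLIP = 35.0
_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class BatchFit:
    """MLE of (alpha, beta) for a batch of genes under one design."""

    alpha: np.ndarray      # (G,) dispersion estimates, exactly 0 at the boundary
    beta: np.ndarray       # (G, p) coefficients in the (reduced) design basis
    loglik: np.ndarray     # (G,) maximized log-likelihood
    converged: np.ndarray  # (G,) bool
    n_params: int          # rank of the design + 1 for the dispersion


def nb_loglik_matrix(R: np.ndarray, MU: np.ndarray, alpha) -> np.ndarray:
    """Log-likelihood per gene (rows) summed over samples (columns).

    ``alpha`` may be a scalar or a per-gene vector; entries below
    ``ALPHA_POISSON`` use the Poisson limit.
    """
    R = np.asarray(R, dtype=float)
    MU = np.asarray(MU, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim == 0:
        alpha = np.full(R.shape[0], float(alpha))
    a = alpha[:, None]
    logmu = np.log(MU)
    pois = R * logmu - MU - gammaln(R + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = 1.0 / np.where(a > 0, a, 1.0)
        nb = (
            gammaln(R + k)
            - gammaln(k)
            - gammaln(R + 1.0)
            + k * np.log(k / (k + MU))
            + R * (logmu - np.log(k + MU))
        )
    out = np.where(a > ALPHA_POISSON, nb, pois)
    return out.sum(axis=1)


def _irls(R, log_s, X, alpha, beta0):
    """Batched IRLS for beta given per-gene alpha.  Returns (beta, converged)."""
    G, _ = R.shape
    p = X.shape[1]
    beta = beta0.copy()
    a = alpha[:, None]
    eye = 1e-10 * np.eye(p)
    converged = np.zeros(G, dtype=bool)
    last_delta = np.full(G, np.inf)
    for _ in range(_IRLS_MAX):
        eta = np.clip(log_s[None, :] + beta @ X.T, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        w = mu / (1.0 + a * mu)
        z = (eta - log_s[None, :]) + (R - mu) / mu
        A = np.einsum("np,gn,nq->gpq", X, w, X, optimize=True) + eye
        b = np.einsum("np,gn->gp", X, w * z, optimize=True)
        new = np.linalg.solve(A, b[..., None])[..., 0]
        new = np.clip(new, -45.0, 45.0)
        last_delta = np.abs(new - beta).max(axis=1)
        beta = new
        if last_delta.max() < _IRLS_TOL:
            break
    converged = last_delta < 1e-6
    return beta, converged


def _profile(R, log_s, X, alpha, beta0):
    """Profile log-likelihood at per-gene alpha: maximize beta, return ll."""
    beta, conv = _irls(R, log_s, X, alpha, beta0)
    eta = np.clip(log_s[None, :] + beta @ X.T, -_ETA_CLIP, _ETA_CLIP)
    ll = nb_loglik_matrix(R, np.exp(eta), alpha)
    return ll, beta, conv


def reduce_design(X: np.ndarray) -> np.ndarray:
    """Drop linearly dependent columns (keeping the leading independent set)."""
    X = np.asarray(X, dtype=float)
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
    return X[:, keep]


def fit_nbglm(R: np.ndarray, sizes: np.ndarray, X: np.ndarray) -> BatchFit:
    """Joint MLE of (alpha_g, beta_g) for all genes under design ``X``.

    ``R`` is (genes x samples) raw counts, ``sizes`` the per-sample library
    sizes used as offsets, ``X`` a design matrix whose first column must be
    the intercept.  Columns that are linearly dependent are dropped before
    fitting (rank collapse, e.g. a duplicated axis).
    """
    R = np.atleast_2d(np.asarray(R, dtype=float))
    sizes = np.asarray(sizes, dtype=float)
    if not np.isfinite(R).all() or not np.isfinite(sizes).all():
        raise ValueError("non-finite counts or library sizes")
    if (sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    if R.shape[1] != sizes.shape[0]:
        raise ValueError("counts and sizes have mismatched sample counts")
    if (R.sum(axis=1) == 0).any():
        raise ValueError("cannot fit genes with all-zero counts; filter first")

    X = reduce_design(X)
    G, _ = R.shape
    p = X.shape[1]
    log_s = np.log(sizes)

    beta0 = np.zeros((G, p))
    beta0[:, 0] = np.log((R.sum(axis=1) + 0.5) / sizes.sum())

    # Poisson boundary (alpha = 0)
    zero = np.zeros(G)
    ll_pois, beta_pois, conv_pois = _profile(R, log_s, X, zero, beta0)

    # coarse profile grid over log(alpha)
    grid = np.linspace(_LOG_ALPHA_LO, _LOG_ALPHA_HI, _N_GRID)
    ll_grid = np.empty((_N_GRID, G))
    beta_prev = beta_pois
    betas_grid = []
    for i, la in enumerate(grid):
        ll_grid[i], beta_prev, _ = _profile(R, log_s, X, np.full(G, np.exp(la)), beta_prev)
        betas_grid.append(beta_prev)
    best = ll_grid.argmax(axis=0)

    # golden-section refinement of each gene's bracketing interval
    step = grid[1] - grid[0]
    lo = grid[best] - step
    hi = np.minimum(grid[best] + step, _LOG_ALPHA_HI)
    beta_ws = np.stack([betas_grid[i][g] for g, i in enumerate(best)])
    c = hi - _INVPHI * (hi - lo)
    d = lo + _INVPHI * (hi - lo)
    fc, beta_ws, _ = _profile(R, log_s, X, np.exp(c), beta_ws)
    fd, beta_ws, _ = _profile(R, log_s, X, np.exp(d), beta_ws)
    for _ in range(_GOLDEN_ITERS):
        left = fc > fd  # keep the interval containing the larger ll
        hi = np.where(left, d, hi)
        lo = np.where(left, lo, c)
        c_new = hi - _INVPHI * (hi - lo)
        d_new = lo + _INVPHI * (hi - lo)
        probe = np.where(left, c_new, d_new)
        f_probe, beta_ws, _ = _profile(R, log_s, X, np.exp(probe), beta_ws)
        fc, fd = np.where(left, f_probe, fd), np.where(left, fc, f_probe)
        c, d = c_new, d_new

    la_hat = 0.5 * (lo + hi)
    alpha_hat = np.exp(la_hat)
    ll_hat, beta_hat, conv_hat = _profile(R, log_s, X, alpha_hat, beta_ws)

    # the Poisson boundary wins whenever it is at least as good
    take_pois = ll_pois >= ll_hat - 1e-10
    alpha = np.where(take_pois, 0.0, alpha_hat)
    loglik = np.where(take_pois, ll_pois, ll_hat)
    beta = np.where(take_pois[:, None], beta_pois, beta_hat)
    converged = np.where(take_pois, conv_pois, conv_hat)
    if (loglik > 1e-6).any():
        raise RuntimeError("log-likelihood of a discrete pmf exceeded 0")
    return BatchFit(alpha=alpha, beta=beta, loglik=loglik,
                    converged=converged.astype(bool), n_params=p + 1)
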