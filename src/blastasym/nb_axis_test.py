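"""Per-gene negative binomial likelihood-ratio tests of axis asymmetry.

For each gene the null model has a single log-mean over all blastomeres
(plus a log library-size offset); the alternative for an axis gives each
pole its own log-mean.  Both models carry a gene-specific NB2 dispersion
estimated jointly with the means by maximum likelihood.  The statistic
-2(l_null - l_alt) is referred to a chi-square with degrees of freedom equal
to the design-rank difference (1 for a single axis, one more per additional
orthogonal axis), and p-values are converted to q-values by Benjamini-
Hochberg within each (axis, mode, embryo) family.

Tests run in two modes: ``pooled`` treats equivalently positioned
blastomeres of different embryos as biological replicates; ``per_embryo``
tests each embryo's eight blastomeres on their own.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from . import _nbglm
from ._nbglm import ALPHA_MAX, ALPHA_POISSON, BatchFit, fit_nbglm, reduce_design
from .count_core import (
    AXES,
    POLES,
    compute_library_sizes,
    filter_testable,
    normalize,
    validate_counts,
    validate_meta,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NBFit",
    "nb_loglik",
    "fit_null",
    "fit_axis",
    "multi_axis_fit",
    "lrt_pvalue",
    "bh_fdr",
    "fold_change",
    "run_tests",
    "BlastomereAsymmetryTest",
]

RESULT_COLUMNS = [
    "gene_id", "axis", "mode", "embryo_id", "lrt_stat", "df", "p", "q",
    "mean_pole_1", "mean_pole_2", "fold", "enriched_pole", "infinite_fold",
    "converged",
]


@dataclass
class NBFit:
    """MLE of one gene under one hypothesis.

    ``betas`` holds per-group log-mean parameters: ``[beta_null]`` for the
    null, ``[beta_pole_1, beta_pole_2]`` for a single axis, and the reduced
    design-basis coefficients for multi-axis fits.
    """

    alpha: float
    betas: np.ndarray
    loglik: float
    converged: bool
    n_params: int
    df_design: int = field(default=1)


def nb_loglik(counts_j, sizes_j, mu_j, alpha: float) -> float:
    """NB2 log-likelihood of one gene (Poisson limit below alpha ~ 1e-8)."""
    r = np.asarray(counts_j, dtype=float)
    mu = np.asarray(mu_j, dtype=float)
    if r.shape != mu.shape:
        raise ValueError("counts and means have different lengths")
    if not (np.isfinite(r).all() and np.isfinite(mu).all() and np.isfinite(alpha)):
        raise ValueError("non-finite inputs to nb_loglik")
    if (mu <= 0).any() or alpha < 0:
        raise ValueError("means must be positive and alpha non-negative")
    return float(_nbglm.nb_loglik_matrix(r[None, :], mu[None, :], float(alpha))[0])


def _single_gene(fit: BatchFit, df_design: int) -> NBFit:
    return NBFit(
        alpha=float(fit.alpha[0]),
        betas=fit.beta[0].copy(),
        loglik=float(fit.loglik[0]),
        converged=bool(fit.converged[0]),
        n_params=fit.n_params,
        df_design=df_design,
    )


def fit_null(counts_j, sizes_j) -> NBFit:
    """Fit the equal-expression null: log mu_j = log s_j + beta_null."""
    r = np.asarray(counts_j, dtype=float)
    s = np.asarray(sizes_j, dtype=float)
    if r.size < 2:
        raise ValueError("need at least two samples")
    X = np.ones((r.size, 1))
    return _single_gene(fit_nbglm(r[None, :], s, X), df_design=1)


def _axis_design(sides: list[np.ndarray]) -> np.ndarray:
    n = sides[0].size
    for a in sides:
        if a.sum() == 0 or a.sum() == a.size:
            raise ValueError("each axis must split the samples non-trivially")
    X = np.column_stack([np.ones(n)] + [a.astype(float) for a in sides])
    return reduce_design(X)


def fit_axis(counts_j, sizes_j, side_j) -> NBFit:
    """Fit the single-axis alternative: separate log-means per pole.

    ``side_j`` is 1 on the second pole of the axis.  The returned ``betas``
    are ``[beta_pole_1, beta_pole_2]``.
    """
    r = np.asarray(counts_j, dtype=float)
    s = np.asarray(sizes_j, dtype=float)
    side = np.asarray(side_j).astype(float)
    X = _axis_design([side])
    fit = fit_nbglm(r[None, :], s, X)
    out = _single_gene(fit, df_design=X.shape[1] - 1)
    b = out.betas
    out.betas = np.array([b[0], b[0] + b[1]])
    return out


def multi_axis_fit(counts_j, sizes_j, sides) -> NBFit:
    """Additive alternative over two or three axes.

    Collinear axis columns collapse (a duplicated axis reduces to the
    single-axis fit); the degrees of freedom against the null equal the
    design-rank difference.
    """
    if not 2 <= len(sides) <= 3:
        raise ValueError("multi-axis fits take two or three axes")
    r = np.asarray(counts_j, dtype=float)
    s = np.asarray(sizes_j, dtype=float)
    X = _axis_design([np.asarray(a).astype(float) for a in sides])
    fit = fit_nbglm(r[None, :], s, X)
    return _single_gene(fit, df_design=X.shape[1] - 1)


def lrt_pvalue(loglik_null: float, loglik_alt: float, df: int) -> tuple[float, float]:
    """Likelihood-ratio statistic and upper chi-square tail probability."""
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = -2.0 * (loglik_null - loglik_alt)
    if stat < -1e-6:
        warnings.warn(
            f"alternative log-likelihood below null by {-stat / 2:.3g}; "
            "optimizer failure, statistic clamped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    stat = max(0.0, stat)
    return stat, float(stats.chi2.sf(stat, df))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(norm_side_a, norm_side_b) -> tuple[float, int | None]:
    """Fold between pole means of normalized expression.

    Returns ``(fold, enriched)`` with ``fold >= 1`` and ``enriched`` 0 or 1
    for the side with the larger mean, ``None`` on an exact tie.  A single
    zero mean yields an infinite fold; two zero means are undefined (NaN).
    """
    a = np.asarray(norm_side_a, dtype=float)
    b = np.asarray(norm_side_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both sides need at least one sample")
    ma, mb = a.mean(), b.mean()
    if ma == mb == 0.0:
        return float("nan"), None
    if ma == mb:
        return 1.0, None
    if min(ma, mb) == 0.0:
        return float("inf"), 0 if ma > mb else 1
    if ma >= mb:
        return ma / mb, 0
    return mb / ma, 1


# ---------------------------------------------------------------------------
# batch pipeline
# ---------------------------------------------------------------------------

def _as_axis_list(axes):
    out = []
    for ax in axes:
        if isinstance(ax, str):
            if ax not in AXES:
                raise ValueError(f"unknown axis {ax!r}")
            out.append((ax,))
        else:
            combo = tuple(ax)
            bad = [a for a in combo if a not in AXES]
            if bad:
                raise ValueError(f"unknown axes {bad!r}")
            out.append(combo)
    return out


def _family_results(counts, norm, sizes, meta, samples, combos, mode, embryo_id):
    """Test one FDR family (one sample set) for every requested axis/combo."""
    R_all = counts.loc[:, samples].to_numpy(dtype=float)
    expressed = R_all.sum(axis=1) > 0
    genes = counts.index[expressed]
    untested = counts.index[~expressed].tolist()
    R = R_all[expressed]
    s = sizes.loc[samples].to_numpy(dtype=float)
    N = norm.loc[genes, samples]

    null_fit = fit_nbglm(R, s, np.ones((len(samples), 1)))
    rows = []
    for combo in combos:
        tag = "+".join(combo)
        sides = [
            (meta.loc[samples, ax] == POLES[ax][1]).to_numpy().astype(float)
            for ax in combo
        ]
        X = _axis_design(sides)
        df = X.shape[1] - 1
        alt = fit_nbglm(R, s, X)

        # guard the nesting l_alt >= l_null: re-profile the alternative at
        # the null's dispersion where the independent optimum fell short
        short = alt.loglik < null_fit.loglik
        if short.any():
            ll2, beta2, conv2 = _nbglm._profile(
                R, np.log(s), X, null_fit.alpha, alt.beta
            )
            better = short & (ll2 > alt.loglik)
            alt.loglik = np.where(better, ll2, alt.loglik)
            alt.beta = np.where(better[:, None], beta2, alt.beta)

        stat = np.maximum(0.0, -2.0 * (null_fit.loglik - alt.loglik))
        pvals = stats.chi2.sf(stat, df)
        ok = null_fit.converged & alt.converged
        q = np.full(len(genes), np.nan)
        if ok.any():
            q[ok] = bh_fdr(pvals[ok])

        if len(combo) == 1:
            ax = combo[0]
            pole_1, pole_2 = POLES[ax]
            side = sides[0].astype(bool)
            m1 = N.loc[:, np.asarray(samples)[~side]].mean(axis=1).to_numpy()
            m2 = N.loc[:, np.asarray(samples)[side]].mean(axis=1).to_numpy()
            with np.errstate(divide="ignore", invalid="ignore"):
                hi = np.maximum(m1, m2)
                lo = np.minimum(m1, m2)
                fold = np.where((hi == 0) & (lo == 0), np.nan, hi / lo)
            enriched = np.select(
                [m1 > m2, m2 > m1], [pole_1, pole_2], default=None
            )
            infinite = np.isinf(fold)
        else:
            m1 = m2 = np.full(len(genes), np.nan)
            fold = np.full(len(genes), np.nan)
            enriched = np.full(len(genes), None)
            infinite = np.zeros(len(genes), dtype=bool)

        rows.append(pd.DataFrame({
            "gene_id": genes,
            "axis": tag,
            "mode": mode,
            "embryo_id": embryo_id,
            "lrt_stat": stat,
            "df": df,
            "p": pvals,
            "q": q,
            "mean_pole_1": m1,
            "mean_pole_2": m2,
            "fold": fold,
            "enriched_pole": enriched,
            "infinite_fold": infinite,
            "converged": ok,
        }))
    return pd.concat(rows, ignore_index=True), untested


def run_tests(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    axes=AXES,
    mode: str = "pooled",
    excluded_ids=(),
    min_count: float = 10.0,
    min_blastomeres: int = 4,
    relaxed: bool = False,
) -> pd.DataFrame:
    """Run the full filter -> fit -> LRT -> BH pipeline; see the estimator."""
    est = BlastomereAsymmetryTest(
        axes=tuple(axes), mode=mode, excluded_ids=tuple(excluded_ids),
        min_count=min_count, min_blastomeres=min_blastomeres, relaxed=relaxed,
    )
    return est.fit(counts, meta).results_


class BlastomereAsymmetryTest(BaseEstimator):
    """Axis-asymmetry screen over a blastomere count matrix.

    Parameters
    ----------
    axes : sequence of axis names ("av", "dv", "lr") or tuples of names
        Single axes are tested with 1 df; a tuple requests the additive
        multi-axis alternative with df equal to the extra design rank.
    mode : "pooled" or "per_embryo"
        Pooled mode treats equivalently positioned blastomeres across
        embryos as replicates; per-embryo mode tests each embryo alone.
    fdr : float
        Threshold applied to q-values by :attr:`significant_`.
    excluded_ids : tuple of str
        Features (e.g. rRNA) removed from library sizes and from testing.
    min_count, min_blastomeres : float, int
        Expression filter: a gene is testable if some single embryo has at
        least ``min_blastomeres`` blastomeres with normalized counts at or
        above ``min_count``.
    relaxed : bool
        Skip the strict 8-blastomere / 4-per-pole design validation.

    Attributes set by :meth:`fit` (trailing underscore): ``results_``,
    ``significant_``, ``tested_genes_``, ``untested_``, ``failed_fits_``,
    ``library_sizes_``, ``normalized_``.
    """

    def __init__(self, axes=AXES, mode="pooled", fdr=0.05, excluded_ids=(),
                 min_count=10.0, min_blastomeres=4, relaxed=False):
        self.axes = axes
        self.mode = mode
        self.fdr = fdr
        self.excluded_ids = excluded_ids
        self.min_count = min_count
        self.min_blastomeres = min_blastomeres
        self.relaxed = relaxed

    def fit(self, counts: pd.DataFrame, meta: pd.DataFrame):
        if self.mode not in ("pooled", "per_embryo"):
            raise ValueError("mode must be 'pooled' or 'per_embryo'")
        counts = validate_counts(counts)
        meta = validate_meta(meta, counts=counts, relaxed=self.relaxed)
        combos = _as_axis_list(self.axes)

        sizes = compute_library_sizes(counts, set(self.excluded_ids))
        norm = normalize(counts, sizes)
        testable = filter_testable(
            norm, meta, min_count=self.min_count,
            min_blastomeres=self.min_blastomeres,
        ).difference(pd.Index(self.excluded_ids))
        self.library_sizes_ = sizes
        self.normalized_ = norm
        self.tested_genes_ = testable
        if len(testable) == 0:
            raise ValueError("no genes pass the expression filter")
        sub = counts.loc[testable]
        nsub = norm.loc[testable]

        families = []
        untested: dict[str, list[str]] = {}
        if self.mode == "pooled":
            samples = list(meta.index)
            res, missed = _family_results(
                sub, nsub, sizes, meta, samples, combos, "pooled", "pooled"
            )
            families.append(res)
            untested["pooled"] = missed
        else:
            for embryo, group in meta.groupby("embryo_id", sort=True):
                res, missed = _family_results(
                    sub, nsub, sizes, meta, list(group.index), combos,
                    "per_embryo", str(embryo),
                )
                families.append(res)
                untested[str(embryo)] = missed

        results = pd.concat(families, ignore_index=True)[RESULT_COLUMNS]
        self.results_ = results
        self.untested_ = untested
        self.failed_fits_ = results.loc[~results["converged"], ["gene_id", "axis", "embryo_id"]]
        self.significant_ = results[results["q"] < self.fdr]
        return self


def write_results(results: pd.DataFrame, path) -> None:
    out = results.copy()
    out["fold"] = out["fold"].map(
        lambda f: "Inf" if np.isinf(f) else f
    )
    out.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    res = pd.read_csv(path, sep="\t")
    res["fold"] = pd.to_numeric(res["fold"].replace("Inf", np.inf))
    return res
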