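"""Reporting layer over axis test results.

Connects the pooled screen with the single-embryo screens: how consistently
is a pooled call replicated embryo-by-embryo, do the fold-changes agree in
direction and magnitude, and is there any embryo pair with *opposing*
significant asymmetry (the diagnostic for a mislabeled dorsal-ventral axis)?

Fold-changes are compared on a signed log scale throughout: the sign encodes
the enriched pole (negative = first pole of the axis, e.g. animal; positive
= second pole, e.g. vegetal), so enrichment at opposite poles never counts
as agreement regardless of magnitude.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .count_core import POLES

__all__ = [
    "signed_log_fold",
    "consistency_table",
    "direction_agreement",
    "within_fold_agreement",
    "opposing_asymmetry_scan",
    "fold_correlation",
    "penetrance",
]


def signed_log_fold(fold, enriched_pole, axis: str = "av") -> np.ndarray:
    """log(fold) signed by pole: positive for the second pole of the axis."""
    fold = np.asarray(fold, dtype=float)
    pole = np.asarray(enriched_pole, dtype=object)
    pole_1, pole_2 = POLES[axis]
    sign = np.where(pole == pole_2, 1.0, np.where(pole == pole_1, -1.0, 0.0))
    with np.errstate(divide="ignore"):
        return sign * np.log(fold)


def _axis_subset(results: pd.DataFrame, axis: str) -> pd.DataFrame:
    sub = results[results["axis"] == axis]
    if sub.empty and not results.empty:
        raise ValueError(f"no rows for axis {axis!r}")
    return sub


def consistency_table(
    pooled: pd.DataFrame,
    per_embryo: pd.DataFrame,
    fdr: float = 0.05,
    axis: str = "av",
    embryo_ids=None,
) -> pd.DataFrame:
    """Single-embryo consistency of pooled calls, with pooled fold summaries.

    For every gene significant in the pooled screen, count the embryos in
    which the same axis is significant at the same FDR, then group by that
    count and the pooled enriched pole, reporting the number of genes and
    the mean and minimum pooled fold-change of each group.
    """
    pooled = _axis_subset(pooled, axis)
    per_embryo = _axis_subset(per_embryo, axis)
    present = set(per_embryo["embryo_id"].unique())
    if embryo_ids is not None:
        missing = set(map(str, embryo_ids)) - present
        if missing:
            raise ValueError(f"per-embryo results missing embryos: {sorted(missing)}")
    n_embryos = len(present)

    hits = pooled[pooled["q"] < fdr]
    if hits.empty:
        return pd.DataFrame(
            columns=["n_embryos_significant", "pole", "n_genes", "avg_fold", "min_fold"]
        )
    sig = per_embryo[per_embryo["q"] < fdr]
    counts = sig.groupby("gene_id").size()

    table = hits[["gene_id", "enriched_pole", "fold"]].copy()
    table["n_sig"] = counts.reindex(table["gene_id"]).fillna(0).astype(int).to_numpy()
    rows = []
    for pole in POLES[axis][::-1]:  # vegetal first, matching reporting convention
        sub = table[table["enriched_pole"] == pole]
        for n in range(n_embryos, -1, -1):
            grp = sub[sub["n_sig"] == n]
            if grp.empty:
                continue
            rows.append({
                "n_embryos_significant": n,
                "pole": pole,
                "n_genes": len(grp),
                "avg_fold": grp["fold"].mean(),
                "min_fold": grp["fold"].min(),
            })
    return pd.DataFrame(rows)


def direction_agreement(
    pooled: pd.DataFrame, per_embryo: pd.DataFrame, fdr: float = 0.05, axis: str = "av"
) -> float:
    """Direction agreement of sub-threshold single-embryo folds.

    Over (gene, embryo) pairs where the gene is pooled-significant but *not*
    significant in that embryo, the fraction whose single-embryo enrichment
    points at the same pole as the pooled call.  NaN when no pair qualifies.
    """
    pooled = _axis_subset(pooled, axis)
    per_embryo = _axis_subset(per_embryo, axis)
    hits = pooled[pooled["q"] < fdr].set_index("gene_id")
    if hits.empty:
        return float("nan")
    sub = per_embryo[per_embryo["gene_id"].isin(hits.index)]
    sub = sub[~(sub["q"] < fdr)]
    if sub.empty:
        return float("nan")
    pooled_pole = hits["enriched_pole"].reindex(sub["gene_id"]).to_numpy()
    agree = (sub["enriched_pole"].to_numpy() == pooled_pole) & pd.notna(pooled_pole)
    return float(np.mean(agree))


def within_fold_agreement(pooled_folds, comparison_folds, factor: float = 2.0) -> float:
    """Fraction of matched signed folds within ``factor`` of each other.

    Inputs are *signed* folds (sign = enriched pole, magnitude >= 1, e.g.
    -2.5 for 2.5-fold enrichment at the first pole).  A pair agrees when the
    magnitudes are within ``factor`` (inclusive) in either direction and the
    directions do not conflict; a flat fold (|f| = 1) is compatible with
    either direction.  NaN on empty or all-NaN input.
    """
    a = np.asarray(pooled_folds, dtype=float)
    b = np.asarray(comparison_folds, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fold vectors must be matched")
    ok = np.isfinite(a) & np.isfinite(b)
    if not ok.any():
        return float("nan")
    a, b = a[ok], b[ok]
    ma, mb = np.abs(a), np.abs(b)
    sign_conflict = (np.sign(a) * np.sign(b) < 0) & (ma != 1.0) & (mb != 1.0)
    ratio = np.maximum(ma / mb, mb / ma)
    return float(np.mean((ratio <= factor) & ~sign_conflict))


def opposing_asymmetry_scan(
    per_embryo: pd.DataFrame, axis: str, fdr: float = 0.05
) -> list[str]:
    """Genes significant in >= 2 embryos with opposite enriched poles.

    The screen for axis-orientation errors: a gene called dorsal in one
    embryo and ventral in another would indicate a flipped label.
    """
    sub = _axis_subset(per_embryo, axis)
    if sub["embryo_id"].nunique() < 2:
        raise ValueError("opposing-asymmetry scan needs at least two embryos")
    sig = sub[(sub["q"] < fdr) & pd.notna(sub["enriched_pole"])]
    out = []
    for gene, grp in sig.groupby("gene_id", sort=True):
        if len(grp) >= 2 and grp["enriched_pole"].nunique() > 1:
            out.append(gene)
    return out


def fold_correlation(folds_a, folds_b, method: str = "spearman") -> float:
    """Rank (or linear) correlation of matched signed folds on the log scale."""
    a = np.asarray(folds_a, dtype=float)
    b = np.asarray(folds_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need matched fold vectors of length >= 3")
    la = np.sign(a) * np.log(np.abs(a))
    lb = np.sign(b) * np.log(np.abs(b))
    if np.allclose(la, la[0]) or np.allclose(lb, lb[0]):
        return float("nan")
    if method == "spearman":
        return float(stats.spearmanr(la, lb).statistic)
    if method == "pearson":
        return float(stats.pearsonr(la, lb).statistic)
    raise ValueError(f"unknown method {method!r}")


def penetrance(n_affected: int, n_injected: int) -> float:
    """Phenotype penetrance as a percentage of treated embryos."""
    if not 0 <= n_affected <= n_injected or n_injected == 0:
        raise ValueError("need 0 <= affected <= injected, injected > 0")
    return 100.0 * n_affected / n_injected
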