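"""Annotation-set enrichment among asymmetric gene cohorts.

The universe is the set of genes that passed the expression filter (i.e.
that could have been called asymmetric), never the whole genome.  For a
cohort (all asymmetric genes, or the genes enriched at one pole) the module
reports the observed number of annotated genes, the chance expectation
``|cohort| * |annotated| / |universe|``, and a Fisher exact p-value on the
2x2 table.  Two-sided tests are the default; this sidedness also reproduces
the published headline enrichment p-values, so it is what the reports use
unless a one-sided alternative is requested explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .count_core import POLES

__all__ = [
    "ContingencyTable",
    "expected_overlap",
    "fisher_exact",
    "enrich_cohorts",
    "read_annotations",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: (in-cohort, out-of-cohort) x (annotated, not annotated)."""

    a: int  # in cohort, annotated
    b: int  # in cohort, not annotated
    c: int  # out of cohort, annotated
    d: int  # out of cohort, not annotated

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def cohort_size(self) -> int:
        return self.a + self.b

    @property
    def annotated_total(self) -> int:
        return self.a + self.c

    @property
    def universe(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_cohort(cls, cohort, annotated, universe) -> "ContingencyTable":
        cohort, annotated, universe = set(cohort), set(annotated), set(universe)
        if not cohort <= universe:
            raise ValueError("cohort is not a subset of the universe")
        annotated &= universe
        a = len(cohort & annotated)
        return cls(
            a=a,
            b=len(cohort) - a,
            c=len(annotated) - a,
            d=len(universe) - len(cohort) - (len(annotated) - a),
        )


def expected_overlap(set_size: int, annotated_total: int, universe: int) -> float:
    """Chance expectation of the overlap between a cohort and an annotation set."""
    if universe <= 0:
        raise ValueError("universe must be positive")
    if set_size > universe or annotated_total > universe:
        raise ValueError("cohort and annotation set cannot exceed the universe")
    return set_size * annotated_total / universe


def fisher_exact(table: ContingencyTable, sided: str = "two") -> float:
    """Exact hypergeometric p-value for a 2x2 table.

    ``sided='two'`` sums the probabilities of all tables with fixed margins
    no more probable than the observed one; ``'greater'`` is the one-sided
    over-representation test.
    """
    alt = {"two": "two-sided", "greater": "greater"}.get(sided)
    if alt is None:
        raise ValueError("sided must be 'two' or 'greater'")
    return float(
        stats.fisher_exact([[table.a, table.b], [table.c, table.d]], alternative=alt).pvalue
    )


def enrich_cohorts(
    results: pd.DataFrame,
    annotations: pd.Series | dict,
    universe,
    axis: str = "av",
    fdr: float = 0.05,
    sided: str = "two",
) -> pd.DataFrame:
    """Enrichment report for the asymmetric and per-pole cohorts.

    ``annotations`` maps gene_id -> 0/1 flag over (at least) the universe;
    ``universe`` is the testable gene set.  Rows: all asymmetric genes, then
    each pole's cohort.
    """
    ann = pd.Series(annotations).astype(int)
    universe = set(universe)
    missing = universe - set(ann.index)
    if missing:
        raise ValueError(f"annotations undefined for {len(missing)} universe genes")
    annotated = {g for g in universe if ann[g] == 1}

    sub = results[(results["axis"] == axis) & (results["q"] < fdr)]
    cohorts = {"asymmetric": set(sub["gene_id"])}
    for pole in POLES[axis]:
        cohorts[pole] = set(sub.loc[sub["enriched_pole"] == pole, "gene_id"])

    rows = []
    for name, cohort in cohorts.items():
        if not cohort <= universe:
            raise ValueError(f"cohort {name!r} is not a subset of the universe")
        tab = ContingencyTable.from_cohort(cohort, annotated, universe)
        p = 1.0 if tab.cohort_size == 0 else fisher_exact(tab, sided=sided)
        rows.append({
            "cohort": name,
            "n_genes": tab.cohort_size,
            "observed_annotated": tab.a,
            "expected_annotated": expected_overlap(
                tab.cohort_size, tab.annotated_total, tab.universe
            ),
            "p": p,
        })
    return pd.DataFrame(rows)


def read_annotations(path) -> pd.Series:
    """TSV with columns gene_id and disease_flag (0/1); extras are ignored."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index("gene_id")["disease_flag"].astype(int)
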