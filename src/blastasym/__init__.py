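"""blastasym: axis asymmetry analysis of single-blastomere RNA-seq counts.

Per-gene negative binomial likelihood-ratio tests of differential transcript
abundance across the animal-vegetal, dorsal-ventral and left-right axes of
8-cell embryos, with library-size normalization, expression filtering,
Benjamini-Hochberg FDR control, pooled and single-embryo modes, consistency
and fold-agreement reporting, disease-annotation enrichment, probe-to-
transcript cross-referencing, and a ground-truth synthetic data generator.
"""

from importlib import resources

import pandas as pd

from .count_core import (
    AXES,
    POLES,
    STANDARD_LIBRARY,
    compute_library_sizes,
    filter_testable,
    normalize,
    read_counts,
    read_meta,
)
from .nb_axis_test import (
    BlastomereAsymmetryTest,
    bh_fdr,
    fit_axis,
    fit_null,
    fold_change,
    lrt_pvalue,
    multi_axis_fit,
    nb_loglik,
    run_tests,
)
from .synthetic_data import SimConfig, simulate

__version__ = "0.1.0"

__all__ = [
    "AXES", "POLES", "STANDARD_LIBRARY",
    "compute_library_sizes", "normalize", "filter_testable",
    "read_counts", "read_meta",
    "BlastomereAsymmetryTest", "run_tests", "nb_loglik", "fit_null",
    "fit_axis", "multi_axis_fit", "lrt_pvalue", "bh_fdr", "fold_change",
    "SimConfig", "simulate",
    "load_consistent_av_genes",
]


def load_consistent_av_genes() -> pd.DataFrame:
    """Reference table of 74 maternal mRNAs called asymmetric on the
    animal-vegetal axis in all five embryos of an 8-cell stage single-
    blastomere screen, with their pooled fold-changes.  Used by the
    reporting-layer validation."""
    path = resources.files("blastasym").joinpath("data/consistent_av_genes.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")
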