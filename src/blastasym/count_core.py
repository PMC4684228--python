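"""Count matrices, sample metadata, library sizes, normalization and the
expression filter.

The data model is deliberately simple: a count matrix is a pandas DataFrame
of non-negative integers with gene identifiers on the rows and blastomere
sample identifiers on the columns; sample metadata is a DataFrame indexed by
sample identifier carrying the embryo of origin and the three binary axis
positions (animal/vegetal, dorsal/ventral, left/right) recorded when the
embryo was disassembled.

Library sizes are column sums of the raw counts after removing excluded
features (ribosomal RNA and other non-gene-model sequences); they serve both
for normalization to a standard library and as offsets in the count models.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Set

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Normalized counts are expressed per this many counted read pairs.
STANDARD_LIBRARY = 25_000_000

#: Embryo axes and the two pole labels of each, in fixed (pole_1, pole_2) order.
POLES: dict[str, tuple[str, str]] = {
    "av": ("animal", "vegetal"),
    "dv": ("dorsal", "ventral"),
    "lr": ("left", "right"),
}

AXES: tuple[str, ...] = tuple(POLES)

META_COLUMNS = ("sample_id", "embryo_id", "av", "dv", "lr")


class DesignError(ValueError):
    """Sample metadata violates the 8-blastomere / 4-per-pole layout."""


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check a count matrix: unique IDs, integral non-negative entries."""
    if counts.index.has_duplicates:
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
    if counts.columns.has_duplicates:
        dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dupes[:5]}")
    values = counts.to_numpy()
    if not np.isfinite(values).all():
        raise ValueError("count matrix contains non-finite entries")
    if (values < 0).any():
        raise ValueError("count matrix contains negative entries")
    if not np.array_equal(values, np.floor(values)):
        raise ValueError("count matrix contains non-integral entries")
    return counts


def validate_meta(
    meta: pd.DataFrame,
    counts: pd.DataFrame | None = None,
    relaxed: bool = False,
) -> pd.DataFrame:
    """Check sample metadata against the expected embryo layout.

    In strict mode every embryo must contribute exactly 8 blastomeres with
    each axis split 4/4.  ``relaxed=True`` only checks labels and identifier
    consistency, which permits deliberately degenerate synthetic designs.
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns and c != meta.index.name]
    if meta.index.name != "sample_id":
        if "sample_id" in meta.columns:
            meta = meta.set_index("sample_id")
        else:
            raise ValueError("metadata needs a sample_id column or index")
    missing = [c for c in ("embryo_id", "av", "dv", "lr") if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing columns: {missing}")
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample identifiers in metadata")
    for axis, poles in POLES.items():
        bad = set(meta[axis].unique()) - set(poles)
        if bad:
            raise ValueError(f"invalid {axis} labels: {sorted(bad)}")
    if counts is not None:
        unknown = meta.index.difference(counts.columns)
        if len(unknown):
            raise ValueError(f"metadata samples absent from counts: {list(unknown)[:5]}")
    if not relaxed:
        for embryo, group in meta.groupby("embryo_id"):
            if len(group) != 8:
                raise DesignError(f"embryo {embryo!r} has {len(group)} blastomeres, expected 8")
            for axis, poles in POLES.items():
                n1 = int((group[axis] == poles[0]).sum())
                if n1 != 4:
                    raise DesignError(
                        f"embryo {embryo!r} axis {axis!r} splits {n1}/{8 - n1}, expected 4/4"
                    )
    return meta


# ---------------------------------------------------------------------------
# I/O — plain TSV throughout
# ---------------------------------------------------------------------------

def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index.name = "gene_id"
    return validate_counts(counts)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_meta(path, counts: pd.DataFrame | None = None, relaxed: bool = False) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    return validate_meta(meta, counts=counts, relaxed=relaxed)


def write_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_exclusions(path) -> set[str]:
    """One feature identifier per line; blank lines ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


# ---------------------------------------------------------------------------
# library sizes, normalization, expression filter
# ---------------------------------------------------------------------------

def compute_library_sizes(
    counts: pd.DataFrame, excluded_ids: Set[str] | Iterable[str] = ()
) -> pd.Series:
    """Per-sample library size: column sum over non-excluded features.

    Excluded identifiers not present in the matrix are ignored with a
    warning.  A zero library size makes the sample unusable as a model
    offset and raises.
    """
    excluded = set(excluded_ids)
    unknown = excluded - set(counts.index)
    if unknown:
        logger.warning("excluded IDs absent from count matrix: %s", sorted(unknown)[:10])
    keep = counts.index.difference(excluded)
    sizes = counts.loc[keep].sum(axis=0).astype(float)
    zero = sizes.index[sizes == 0].tolist()
    if zero:
        raise ValueError(f"zero library size for sample(s) {zero}; cannot be used as offsets")
    sizes.name = "library_size"
    return sizes


def normalize(counts: pd.DataFrame, sizes: pd.Series) -> pd.DataFrame:
    """Scale raw counts to a standard library of 25 million counted reads."""
    missing = counts.columns.difference(sizes.index)
    if len(missing):
        raise ValueError(f"library sizes missing for sample(s): {list(missing)}")
    factors = STANDARD_LIBRARY / sizes.reindex(counts.columns)
    return counts.astype(float).mul(factors, axis=1)


def filter_testable(
    norm: pd.DataFrame,
    meta: pd.DataFrame,
    min_count: float = 10.0,
    min_blastomeres: int = 4,
) -> pd.Index:
    """Genes with >= ``min_count`` normalized reads in >= ``min_blastomeres``
    blastomeres of at least one embryo.

    The condition is evaluated within each embryo separately — qualifying
    blastomeres spread across embryos do not count.  Both thresholds are
    inclusive.
    """
    unmapped = norm.columns.difference(meta.index)
    if len(unmapped):
        raise ValueError(f"samples without embryo metadata: {list(unmapped)[:5]}")
    keep = np.zeros(norm.shape[0], dtype=bool)
    for _, group in meta.groupby("embryo_id"):
        cols = norm.columns.intersection(group.index)
        if not len(cols):
            continue
        qualifying = (norm[cols].to_numpy() >= min_count).sum(axis=1)
        keep |= qualifying >= min_blastomeres
    return norm.index[keep]
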