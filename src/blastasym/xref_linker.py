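"""Resolve microarray probe-set identifiers to reference transcript IDs.

Works on pre-computed BLAST tabular hit files (outfmt-6-style) plus a table
of paired-end links between assembled EST clusters.  For each probe three
kinds of route to a reference transcript are enumerated:

* ``direct``             probe -> transcript
* ``via_cluster``        probe -> EST cluster -> transcript
* ``via_paired_clusters`` probe -> cluster -> (paired-end link) -> cluster -> transcript

Each route terminal counts as one vote; a probe is ``accepted`` when one
transcript holds a strict majority (> 50%) of the votes, ``ambiguous`` when
there are votes but no strict majority, and ``unidentified`` when there are
no routes at all.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "read_blast_tab",
    "filter_hits",
    "compute_routes",
    "resolve",
    "resolve_all",
    "XrefCall",
]

HIT_COLUMNS = ["query_id", "target_id", "percent_identity", "e_value", "bit_score"]

_OUTFMT6 = [
    "query_id", "target_id", "percent_identity", "length", "mismatch",
    "gapopen", "qstart", "qend", "sstart", "send", "e_value", "bit_score",
]


@dataclass
class XrefCall:
    probe_id: str
    status: str                      # accepted | ambiguous | unidentified
    target_id: str | None = None     # set only when accepted
    routes: list = field(default_factory=list)


def read_blast_tab(path) -> pd.DataFrame:
    """Read a 12-column BLAST tabular (outfmt 6) file."""
    df = pd.read_csv(path, sep="\t", header=None, names=_OUTFMT6, comment="#")
    return df[HIT_COLUMNS]


def filter_hits(
    hits: pd.DataFrame, e_max: float = 1e-20, id_min: float = 85.0
) -> pd.DataFrame:
    """Apply e-value and identity cut-offs, then keep the best hit per
    (query, target) pair: highest bit score, ties broken by lower e-value,
    then lexicographic target."""
    if hits.empty:
        return hits.copy()
    kept = hits[(hits["e_value"] <= e_max) & (hits["percent_identity"] >= id_min)]
    kept = kept.sort_values(
        ["query_id", "target_id", "bit_score", "e_value"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    return kept.drop_duplicates(["query_id", "target_id"], keep="first").reset_index(drop=True)


def _targets_of(hits: pd.DataFrame, query: str) -> list[str]:
    if hits is None or hits.empty:
        return []
    return sorted(hits.loc[hits["query_id"] == query, "target_id"].tolist())


def _check_pair_links(pair_links: pd.DataFrame) -> dict[str, set[str]]:
    """Adjacency of the undirected pair-link graph; error on any cycle."""
    adj: dict[str, set[str]] = {}
    if pair_links is None or len(pair_links) == 0:
        return adj
    parent: dict[str, str] = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pair_links[["cluster_a", "cluster_b"]].itertuples(index=False):
        ra, rb = find(a), find(b)
        if ra == rb:
            raise ValueError(f"cyclic paired-end links involving {a!r} and {b!r}")
        parent[ra] = rb
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def compute_routes(
    probe_id: str,
    direct_hits: pd.DataFrame,
    cluster_hits,
    cluster_to_ref_hits: pd.DataFrame,
    pair_links: pd.DataFrame | None = None,
) -> list[tuple[str, str]]:
    """All (route_type, terminal transcript) routes for one probe.

    ``cluster_hits`` is one probe->cluster hit table or a list of them (one
    per EST build).  Duplicate terminals reached by distinct routes are kept
    — they are independent votes.
    """
    if isinstance(cluster_hits, pd.DataFrame):
        cluster_hits = [cluster_hits]
    adj = _check_pair_links(pair_links)

    routes: list[tuple[str, str]] = []
    for target in _targets_of(direct_hits, probe_id):
        routes.append(("direct", target))
    for table in cluster_hits:
        for cluster in _targets_of(table, probe_id):
            for target in _targets_of(cluster_to_ref_hits, cluster):
                routes.append(("via_cluster", target))
            for mate in sorted(adj.get(cluster, ())):
                for target in _targets_of(cluster_to_ref_hits, mate):
                    routes.append(("via_paired_clusters", target))
    return routes


def resolve(routes, probe_id: str = "") -> XrefCall:
    """Strict-majority vote over route terminals."""
    routes = list(routes)
    if not routes:
        return XrefCall(probe_id=probe_id, status="unidentified", routes=[])
    votes = Counter(t for _, t in routes)
    target, top = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
    if top * 2 > len(routes):
        return XrefCall(probe_id=probe_id, status="accepted", target_id=target, routes=routes)
    return XrefCall(probe_id=probe_id, status="ambiguous", routes=routes)


def resolve_all(
    probe_ids,
    direct_hits: pd.DataFrame,
    cluster_hits,
    cluster_to_ref_hits: pd.DataFrame,
    pair_links: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Resolve every probe; returns probe_id, status, target_id, n_routes."""
    rows = []
    for probe in probe_ids:
        call = resolve(
            compute_routes(probe, direct_hits, cluster_hits, cluster_to_ref_hits, pair_links),
            probe_id=probe,
        )
        rows.append({
            "probe_id": probe,
            "status": call.status,
            "target_id": call.target_id,
            "n_routes": len(call.routes),
        })
    return pd.DataFrame(rows)
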