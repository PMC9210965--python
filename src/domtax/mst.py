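"""Step 3 — MST construction, taxonomy clustering and agreement metrics.

The complete species graph weighted by pairwise distance is reduced to its
minimum spanning tree with Prim's algorithm. The tree is then compared to a
reference taxonomy at a chosen rank: retaining only edges whose endpoints
share the rank label, each taxon falls apart into one or more connected
groups, and three concordance standards summarize how well the tree
respects the taxonomy:

* **arithmetic percentage** — ΣS_i / ΣT_i, where T_i is taxon i's species
  count and S_i the number of its species outside its largest group;
* **weighted percentage** — the per-taxon mean of S_i / T_i;
* **split-taxon count** — the number of taxa broken into more than one
  group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from domtax.distances import DISTANCE_MODELS, DistanceMatrix
from domtax.io import REQUIRED_RANKS, TaxonomyRecord
from domtax.profiles import STATISTICAL_MODELS


@dataclass(frozen=True)
class MSTree:
    """A minimum spanning tree over species: n − 1 weighted edges."""

    species_ids: list[str]
    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        n = len(self.species_ids)
        if len(self.edges) != max(n - 1, 0):
            raise ValueError(f"{n} nodes require {n - 1} edges, got {len(self.edges)}")

    @property
    def total_weight(self) -> float:
        return sum(w for _, _, w in self.edges)


@dataclass(frozen=True)
class TaxonGroup:
    """A maximal connected set of same-taxon species on the MST."""

    taxon: str
    member_ids: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class TaxonClusterReport:
    """Per-taxon group structure plus the three agreement metrics."""

    entries: list[dict]
    metrics: dict


def build_mst_prim(matrix: DistanceMatrix) -> MSTree:
    """Build the minimum spanning tree with Prim's algorithm.

    The start node is the lexicographically smallest species ID; at each
    step the frontier edge of minimal weight joins the tree, ties broken
    by (weight, lexicographically smaller in-tree endpoint, smaller new
    endpoint), so the result is deterministic even when the MST is not
    unique. The total weight always equals the global minimum.
    """
    matrix.validate()
    ids = matrix.species_ids
    values = matrix.values
    n = len(ids)
    if n == 0:
        raise ValueError("cannot build an MST over zero species")
    order = sorted(range(n), key=lambda i: ids[i])
    start = order[0]
    in_tree = {start}
    # best known edge into each out-of-tree node: (weight, in-tree id, index)
    best: dict[int, tuple[float, str]] = {
        j: (values[start, j], ids[start]) for j in range(n) if j != start
    }
    edges: list[tuple[str, str, float]] = []
    while best:
        j = min(best, key=lambda k: (best[k][0], best[k][1], ids[k]))
        w, u = best.pop(j)
        edges.append((u, ids[j], float(w)))
        in_tree.add(j)
        for k, (wk, uk) in best.items():
            cand = values[j, k]
            if cand < wk or (cand == wk and ids[j] < uk):
                best[k] = (float(cand), ids[j])
    return MSTree(species_ids=list(ids), edges=edges)


def _rank_label(
    species_id: str, taxonomy: Mapping[str, TaxonomyRecord], rank: str
) -> str:
    rec = taxonomy.get(species_id)
    name = rec.rank(rank) if rec is not None else None
    # species without the rank get a unique singleton label so the
    # partition still covers every node
    return name if name else f"__unranked__{species_id}"


def cluster_by_taxon(
    tree: MSTree, taxonomy: Mapping[str, TaxonomyRecord], rank: str = "phylum"
) -> list[TaxonGroup]:
    """Partition the MST into same-taxon connected groups at a rank.

    Only edges whose two endpoints share the rank label are retained; the
    groups are the connected components of that subgraph, so two
    same-taxon nodes joined only through a different taxon stay in
    separate groups. Every species lands in exactly one group and the
    result is independent of traversal order.
    """
    if rank not in REQUIRED_RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {REQUIRED_RANKS}")
    labels = {sid: _rank_label(sid, taxonomy, rank) for sid in tree.species_ids}
    graph = nx.Graph()
    graph.add_nodes_from(tree.species_ids)
    for u, v, _ in tree.edges:
        if labels[u] == labels[v]:
            graph.add_edge(u, v)
    groups = []
    for component in nx.connected_components(graph):
        members = tuple(sorted(component))
        groups.append(TaxonGroup(taxon=labels[members[0]], member_ids=members))
    # deterministic report order: by taxon, then largest group first
    groups.sort(key=lambda g: (g.taxon, -g.size, g.member_ids))
    return groups


def isolation_counts(groups: Sequence[TaxonGroup]) -> dict[str, tuple[int, int]]:
    """Per-taxon isolated-species counts: taxon → (S_i, T_i).

    T_i sums all of taxon i's group sizes; S_i = T_i − size of the largest
    group (the taxon's "main part"). When two groups tie for largest, the
    first under descending-size-then-lexicographic ordering is the main
    part; S_i is unaffected by that choice.
    """
    sizes: dict[str, list[int]] = {}
    for g in groups:
        sizes.setdefault(g.taxon, []).append(g.size)
    counts = {}
    for taxon, group_sizes in sizes.items():
        total = sum(group_sizes)
        counts[taxon] = (total - max(group_sizes), total)
    return counts


def agreement_metrics(
    counts: Mapping[str, tuple[int, int]],
) -> tuple[float, float, int]:
    """The three taxonomy-agreement standards from per-taxon (S_i, T_i).

    Returns (arithmetic percentage, weighted percentage, split-taxon
    count) where arithmetic = ΣS_i / ΣT_i, weighted = mean over taxa of
    S_i / T_i, and the split count is the number of taxa with isolated
    species (equivalently, broken into ≥ 2 groups). Percentages are
    fractions in [0, 1].
    """
    if not counts:
        raise ValueError("need at least one taxon")
    for taxon, (s, t) in counts.items():
        if t <= 0:
            raise ValueError(f"taxon {taxon!r} has non-positive species count {t}")
        if not 0 <= s <= t:
            raise ValueError(f"taxon {taxon!r} has S={s} outside [0, T={t}]")
    total_s = sum(s for s, _ in counts.values())
    total_t = sum(t for _, t in counts.values())
    arithmetic = total_s / total_t
    weighted = sum(s / t for s, t in counts.values()) / len(counts)
    split = sum(1 for s, _ in counts.values() if s > 0)
    return arithmetic, weighted, split


def build_cluster_report(groups: Sequence[TaxonGroup]) -> TaxonClusterReport:
    """Assemble the per-taxon report and metrics from a group partition."""
    counts = isolation_counts(groups)
    sizes: dict[str, list[int]] = {}
    for g in groups:
        sizes.setdefault(g.taxon, []).append(g.size)
    entries = []
    for taxon in sorted(counts):
        s, t = counts[taxon]
        entries.append(
            {
                "taxon": taxon,
                "T": t,
                "S": s,
                "group_sizes": sorted(sizes[taxon], reverse=True),
            }
        )
    arithmetic, weighted, split = agreement_metrics(counts)
    metrics = {
        "arithmetic_percentage": arithmetic,
        "weighted_percentage": weighted,
        "split_taxon_count": split,
    }
    return TaxonClusterReport(entries=entries, metrics=metrics)


def enumerate_combinations() -> list[tuple[str, str]]:
    """All 12 (statistical model, distance model) combinations, in
    canonical order."""
    return list(product(STATISTICAL_MODELS, DISTANCE_MODELS))
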