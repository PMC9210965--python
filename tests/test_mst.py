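import random

import networkx as nx
import numpy as np
import pytest

from domtax.distances import DistanceMatrix
from domtax.io import TaxonomyRecord
from domtax.mst import (
    MSTree,
    TaxonGroup,
    agreement_metrics,
    build_cluster_report,
    build_mst_prim,
    cluster_by_taxon,
    enumerate_combinations,
    isolation_counts,
)


def matrix_from(ids, pairs):
    n = len(ids)
    values = np.zeros((n, n))
    index = {s: i for i, s in enumerate(ids)}
    for (u, v), w in pairs.items():
        values[index[u], index[v]] = values[index[v], index[u]] = w
    return DistanceMatrix(ids, values, "content", "jaccard")


def taxonomy(labels):
    return {
        sid: TaxonomyRecord(species_id=sid, lineage={"phylum": phylum})
        for sid, phylum in labels.items()
    }


class TestPrimMST:
    def test_three_node_triangle(self):
        # all three spanning trees enumerable by hand; {A-B, A-C} is minimal
        m = matrix_from(["A", "B", "C"], {("A", "B"): 0.1, ("A", "C"): 0.2, ("B", "C"): 0.3})
        tree = build_mst_prim(m)
        assert {(u, v) for u, v, _ in tree.edges} == {("A", "B"), ("A", "C")}
        assert tree.total_weight == pytest.approx(0.3)

    def test_two_nodes(self):
        tree = build_mst_prim(matrix_from(["A", "B"], {("A", "B"): 0.4}))
        assert tree.edges == [("A", "B", 0.4)]

    def test_single_node(self):
        tree = build_mst_prim(matrix_from(["A"], {}))
        assert tree.edges == []

    def test_matches_kruskal_oracle_total_weight(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(3, 30))
            raw = rng.uniform(0, 1, size=(n, n))
            values = (raw + raw.T) / 2
            np.fill_diagonal(values, 0.0)
            ids = [f"s{i:02d}" for i in range(n)]
            tree = build_mst_prim(DistanceMatrix(ids, values, "content", "jaccard"))
            g = nx.from_numpy_array(values)
            oracle = nx.minimum_spanning_tree(g, algorithm="kruskal")
            assert tree.total_weight == pytest.approx(
                oracle.size(weight="weight"), abs=1e-9
            )

    def test_deterministic_under_ties(self):
        ids = ["A", "B", "C", "D"]
        values = np.full((4, 4), 0.5)
        np.fill_diagonal(values, 0.0)
        m = DistanceMatrix(ids, values, "content", "jaccard")
        assert build_mst_prim(m).edges == build_mst_prim(m).edges
        # all weights tie: lexicographic rule attaches everything to A
        assert {(u, v) for u, v, _ in build_mst_prim(m).edges} == {
            ("A", "B"), ("A", "C"), ("A", "D"),
        }

    def test_asymmetric_matrix_rejected(self):
        values = np.array([[0.0, 0.2], [0.3, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            build_mst_prim(DistanceMatrix(["A", "B"], values, "content", "jaccard"))

    def test_invalid_edge_count_rejected(self):
        with pytest.raises(ValueError, match="edges"):
            MSTree(species_ids=["A", "B", "C"], edges=[("A", "B", 0.1)])


PATH_TREE = MSTree(
    species_ids=["A1", "A2", "B1", "A3"],
    edges=[("A1", "A2", 0.1), ("A2", "B1", 0.2), ("B1", "A3", 0.3)],
)
PATH_TAX = taxonomy({"A1": "A", "A2": "A", "B1": "B", "A3": "A"})


class TestClusterByTaxon:
    def test_path_with_interrupting_phylum_splits(self):
        groups = cluster_by_taxon(PATH_TREE, PATH_TAX, rank="phylum")
        members = sorted(g.member_ids for g in groups)
        assert members == [("A1", "A2"), ("A3",), ("B1",)]
        assert sum(1 for g in groups if g.taxon == "A") == 2

    def test_single_phylum_single_group(self):
        tax = taxonomy({sid: "A" for sid in PATH_TREE.species_ids})
        groups = cluster_by_taxon(PATH_TREE, tax, rank="phylum")
        assert len(groups) == 1
        assert set(groups[0].member_ids) == set(PATH_TREE.species_ids)

    def test_star_with_foreign_center(self):
        tree = MSTree(
            species_ids=["C1", "B1", "B2"],
            edges=[("C1", "B1", 0.1), ("C1", "B2", 0.1)],
        )
        groups = cluster_by_taxon(tree, taxonomy({"C1": "A", "B1": "B", "B2": "B"}))
        assert len(groups) == 3  # B1 and B2 connect only through phylum A

    def test_partition_independent_of_node_order(self):
        rnd = random.Random(3)
        expected = sorted(g.member_ids for g in cluster_by_taxon(PATH_TREE, PATH_TAX))
        for _ in range(5):
            ids = PATH_TREE.species_ids[:]
            edges = PATH_TREE.edges[:]
            rnd.shuffle(ids)
            rnd.shuffle(edges)
            shuffled = MSTree(species_ids=ids, edges=edges)
            assert sorted(g.member_ids for g in cluster_by_taxon(shuffled, PATH_TAX)) == expected

    def test_missing_rank_gets_singleton_label(self):
        tax = dict(PATH_TAX)
        tax["A3"] = TaxonomyRecord(species_id="A3", lineage={})
        groups = cluster_by_taxon(PATH_TREE, tax, rank="phylum")
        singleton = [g for g in groups if g.member_ids == ("A3",)]
        assert len(singleton) == 1
        assert singleton[0].taxon.startswith("__unranked__")

    def test_unknown_rank_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            cluster_by_taxon(PATH_TREE, PATH_TAX, rank="kingdom")


class TestIsolationCounts:
    @pytest.mark.parametrize(
        "sizes,expected",
        [([4, 1], (1, 5)), ([3], (0, 3)), ([2, 2], (2, 4))],
    )
    def test_counts(self, sizes, expected):
        groups = [
            TaxonGroup(taxon="A", member_ids=tuple(f"g{i}m{j}" for j in range(n)))
            for i, n in enumerate(sizes)
        ]
        assert isolation_counts(groups)["A"] == expected


class TestAgreementMetrics:
    def test_worked_example(self):
        arithmetic, weighted, split = agreement_metrics({"A": (1, 5), "B": (0, 3)})
        assert arithmetic == pytest.approx(0.125)
        assert weighted == pytest.approx(0.1)
        assert split == 1

    def test_perfect_concordance(self):
        assert agreement_metrics({"A": (0, 4), "B": (0, 2)}) == (0.0, 0.0, 0)

    @pytest.mark.parametrize("k", [2, 5, 9])
    def test_fully_split_taxon_closed_form(self, k):
        arithmetic, weighted, split = agreement_metrics({"A": (k - 1, k)})
        assert arithmetic == pytest.approx((k - 1) / k)
        assert weighted == pytest.approx((k - 1) / k)
        assert split == 1

    def test_identities_on_random_partitions(self):
        """ΣS/ΣT and mean(S_i/T_i) recomputed directly from random
        group-size partitions must match the metric outputs."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            counts = {}
            for t in range(int(rng.integers(1, 8))):
                sizes = rng.integers(1, 6, size=int(rng.integers(1, 5)))
                counts[f"tax{t}"] = (int(sizes.sum() - sizes.max()), int(sizes.sum()))
            arithmetic, weighted, split = agreement_metrics(counts)
            ss = sum(s for s, _ in counts.values())
            tt = sum(t for _, t in counts.values())
            assert arithmetic == pytest.approx(ss / tt)
            assert weighted == pytest.approx(
                np.mean([s / t for s, t in counts.values()])
            )
            assert split == sum(s > 0 for s, _ in counts.values())
            assert (arithmetic == 0) == (weighted == 0) == (split == 0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            agreement_metrics({"A": (0, 0)})

    def test_cluster_report_from_path_example(self):
        groups = cluster_by_taxon(PATH_TREE, PATH_TAX)
        report = build_cluster_report(groups)
        by_taxon = {e["taxon"]: e for e in report.entries}
        assert by_taxon["A"]["T"] == 3 and by_taxon["A"]["S"] == 1
        assert by_taxon["A"]["group_sizes"] == [2, 1]
        assert by_taxon["B"]["T"] == 1 and by_taxon["B"]["S"] == 0
        assert report.metrics["arithmetic_percentage"] == pytest.approx(0.25)
        assert report.metrics["split_taxon_count"] == 1


class TestEnumerateCombinations:
    def test_cross_product(self):
        combos = enumerate_combinations()
        assert len(combos) == 12
        assert len(set(combos)) == 12
        assert ("organization", "jaccard") in combos
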