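"""Genus/species/cluster assignment and pangenome partitioning."""

import itertools

import numpy as np
import pandas as pd
import pytest

from phagetax.protein_clustering import ProteinGroup
from phagetax.taxonomy import (
    SINGLETON,
    assign_clusters,
    assign_subclusters,
    classify,
    make_assignments,
    pangenome_partition,
    write_taxonomy_report,
)


def sim_df(ids, pairs, default=0.0):
    ids = list(ids)
    n = len(ids)
    mat = pd.DataFrame(np.full((n, n), default), index=ids, columns=ids)
    np.fill_diagonal(mat.values, 100.0)
    for (a, b), v in pairs.items():
        mat.loc[a, b] = mat.loc[b, a] = v
    return mat


class TestSubclusters:
    def test_tight_trio_is_one_species(self):
        m = sim_df("abc", {("a", "b"): 96, ("b", "c"): 96, ("a", "c"): 97})
        subclusters, species = assign_subclusters(m)
        assert subclusters == [["a", "b", "c"]]
        assert species == [["a", "b", "c"]]

    def test_single_linkage_chain(self):
        m = sim_df("abc", {("a", "b"): 70, ("b", "c"): 70, ("a", "c"): 40})
        subclusters, _ = assign_subclusters(m)
        assert subclusters == [["a", "b", "c"]]

    def test_all_below_threshold(self):
        m = sim_df("abc", {("a", "b"): 40, ("b", "c"): 50, ("a", "c"): 30})
        subclusters, species = assign_subclusters(m)
        assert subclusters == [["a"], ["b"], ["c"]]
        assert species == [["a"], ["b"], ["c"]]

    def test_species_nest_within_subclusters(self):
        m = sim_df(
            "abcd",
            {("a", "b"): 96, ("b", "c"): 70, ("c", "d"): 40, ("a", "c"): 70},
        )
        subclusters, species = assign_subclusters(m)
        for sp in species:
            assert any(set(sp) <= set(sc) for sc in subclusters)

    def test_asymmetric_matrix_rejected(self):
        m = sim_df("ab", {("a", "b"): 70})
        m.iloc[0, 1] = 71.0
        with pytest.raises(ValueError, match="symmetric"):
            assign_subclusters(m)

    @pytest.mark.parametrize("seed", range(5))
    def test_threshold_monotonicity(self, seed):
        """Raising the genus threshold only refines the partition."""
        rng = np.random.default_rng(seed)
        ids = [f"g{i}" for i in range(8)]
        raw = rng.uniform(0, 100, size=(8, 8))
        mat = pd.DataFrame((raw + raw.T) / 2, index=ids, columns=ids)
        np.fill_diagonal(mat.values, 100.0)
        coarse, _ = assign_subclusters(mat, genus_threshold=40)
        fine, _ = assign_subclusters(mat, genus_threshold=70)
        for part in fine:
            assert any(set(part) <= set(whole) for whole in coarse)


class TestClusters:
    def test_two_subclusters_above_threshold_merge(self):
        shared = sim_df("abcd", {p: 40 for p in itertools.combinations("abcd", 2)})
        shared.loc["a", "b"] = shared.loc["b", "a"] = 90
        shared.loc["c", "d"] = shared.loc["d", "c"] = 90
        clusters, _ = assign_clusters(shared, [["a", "b"], ["c", "d"]])
        assert clusters == [["a", "b", "c", "d"]]

    def test_two_subclusters_below_threshold_stay_apart(self):
        shared = sim_df("abcd", {p: 10 for p in itertools.combinations("abcd", 2)})
        shared.loc["a", "b"] = shared.loc["b", "a"] = 90
        shared.loc["c", "d"] = shared.loc["d", "c"] = 90
        clusters, _ = assign_clusters(shared, [["a", "b"], ["c", "d"]])
        assert clusters == [["a", "b"], ["c", "d"]]

    def test_subcluster_atomicity_enforced(self, caplog):
        """If the dendrogram cut would split a sub-cluster, the offending
        branches are merged back and a warning logged."""
        shared = sim_df(
            "abc", {("a", "b"): 80, ("b", "c"): 25, ("a", "c"): 25}
        )
        with caplog.at_level("WARNING"):
            clusters, _ = assign_clusters(shared, [["a", "b", "c"]])
        assert clusters == [["a", "b", "c"]]
        assert "merging" in caplog.text

    def test_partition_mismatch_rejected(self):
        shared = sim_df("ab", {("a", "b"): 50})
        with pytest.raises(ValueError, match="cover"):
            assign_clusters(shared, [["a"]])

    def test_planted_demo_population_recovered(self, demo_results):
        truth = demo_results["truth"]
        amap = {a.genome_id: a for a in demo_results["assignments"]}
        by_planted_cluster = {}
        for gid, (cl, ge, sp) in truth.taxa.items():
            by_planted_cluster.setdefault(cl, set()).add(amap[gid].cluster_id)
        for cl, labels in by_planted_cluster.items():
            assert len(labels) == 1, f"planted cluster {cl} split into {labels}"
        planted_singletons = {g for g, t in truth.taxa.items() if t[0].startswith("SGL")}
        recovered = {a.genome_id for a in demo_results["assignments"] if a.singleton}
        assert recovered == planted_singletons


class TestLabels:
    def test_deterministic_letters_and_numbers(self):
        subclusters = [["a", "b"], ["c"], ["d"]]
        species = [["a"], ["b"], ["c"], ["d"]]
        clusters = [["a", "b", "c"], ["d"]]
        assignments = make_assignments(subclusters, species, clusters)
        amap = {a.genome_id: a for a in assignments}
        assert amap["a"].label == "A1"
        assert amap["b"].label == "A1"
        assert amap["c"].label == "A2"
        assert amap["d"].cluster_id == SINGLETON
        assert amap["d"].singleton

    def test_nestedness(self, demo_results):
        for a in demo_results["assignments"]:
            if not a.singleton:
                assert a.subcluster_id.startswith(a.cluster_id)
                assert a.species_id.startswith(a.subcluster_id)


class TestPangenome:
    def _groups(self, spec):
        """spec: list of (group_id, {genome: n_proteins})"""
        groups = []
        for gid, members in spec:
            prot = frozenset(
                f"{g}_{gid}_{k}" for g, n in members.items() for k in range(n)
            )
            groups.append(ProteinGroup(gid, prot, frozenset(members)))
        protein_genomes = {
            p: p.split("_")[0] for g in groups for p in g.members
        }
        return groups, protein_genomes

    def test_core_accessory_unique_definitions(self):
        groups, pg = self._groups(
            [
                ("core1", {"a": 1, "b": 1, "c": 1}),
                ("acc1", {"a": 1, "b": 1}),
                ("uni1", {"c": 2}),
            ]
        )
        s = pangenome_partition("X", ["a", "b", "c"], groups, pg)
        assert (s.n_core, s.n_accessory, s.n_unique) == (1, 1, 2)
        assert s.n_core_exclusive == 1

    def test_every_group_classified_exactly_once(self, demo_results):
        groups = demo_results["groups"]
        pg = demo_results["protein_genomes"]
        for summary in demo_results["summaries"]:
            if summary.n_genomes == 1:
                continue
            members = {
                a.genome_id
                for a in demo_results["assignments"]
                if a.cluster_id == summary.cluster_id
            }
            in_cluster = [g for g in groups if g.genomes & members]
            single = [
                g for g in in_cluster
                if len({pg[m] for m in g.members if pg[m] in members}) == 1
            ]
            assert summary.n_core + summary.n_accessory + len(single) == len(in_cluster)

    def test_single_genome_cluster_reports_na(self):
        groups, pg = self._groups(
            [("uni", {"a": 3}), ("shared", {"a": 1, "z": 1})]
        )
        s = pangenome_partition("S", ["a"], groups, pg)
        assert s.n_core is None and s.n_accessory is None
        assert s.n_unique == 3
        assert s.n_shared == 1

    def test_partial_genome_excluded_from_core_denominator(self):
        groups, pg = self._groups(
            [("g1", {"a": 1, "b": 1}), ("g2", {"a": 1, "b": 1, "p": 1})]
        )
        s = pangenome_partition("X", ["a", "b", "p"], groups, pg, partial={"p"})
        assert s.n_core == 2  # both groups cover all non-partial members

    def test_planted_core_accessory_unique_counts(self, demo_results):
        """Planted per-cluster design: 6 core families (1 shared between
        clusters), 5 accessory per genus, 1 private gene per genome."""
        for s in demo_results["summaries"]:
            if s.n_genomes == 1:
                continue
            assert (s.n_core, s.n_accessory, s.n_unique) == (6, 10, 6)
            assert s.n_core_exclusive == 5

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pangenome_partition("X", [], [], {})


def test_report_round_trip_and_determinism(tmp_path, demo_results):
    a1, s1 = tmp_path / "tax1.tsv", tmp_path / "pan1.tsv"
    a2, s2 = tmp_path / "tax2.tsv", tmp_path / "pan2.tsv"
    write_taxonomy_report(
        demo_results["assignments"], demo_results["summaries"], a1, s1
    )
    write_taxonomy_report(
        demo_results["assignments"], demo_results["summaries"], a2, s2
    )
    assert a1.read_bytes() == a2.read_bytes()
    assert s1.read_bytes() == s2.read_bytes()
    rows = a1.read_text().splitlines()
    assert len(rows) == len(demo_results["assignments"]) + 1
    pan = pd.read_csv(s1, sep="\t", keep_default_na=False)
    assert {"N/A"} <= set(pan["n_core"].astype(str))  # singleton rows present


def test_classify_end_to_end_consistency(demo_results):
    assignments, clusters, _ = classify(demo_results["sim"], demo_results["shared"])
    assert [a.label for a in assignments] == [
        a.label for a in demo_results["assignments"]
    ]
    covered = sorted(g for c in clusters for g in c)
    assert covered == sorted(demo_results["sim"].index)
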