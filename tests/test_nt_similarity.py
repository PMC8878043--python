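"""Seed-and-extend alignment, HSP merging and intergenomic similarity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracle_utils import sw_nt_identities
from phagetax import synthetic_data as sd
from phagetax.genome_io import GenomeRecord, reverse_complement
from phagetax.nt_similarity import (
    AlignmentHSP,
    ScoringParams,
    align_pair,
    divergence_from_identity,
    intergenomic_similarity,
    merge_hsps,
    pairwise_identity,
    similarity_matrix,
)


def random_dna(length, seed):
    return "".join(np.random.default_rng(seed).choice(list("ACGT"), size=length))


def mutate(seq, d, seed):
    rng = np.random.default_rng(seed)
    out = list(seq)
    for i in np.nonzero(rng.random(len(out)) < d)[0]:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


class TestAlignPair:
    def test_self_alignment_full_length(self):
        seq = random_dna(1000, 1)
        hsps = align_pair(seq, seq)
        top = hsps[0]
        assert (top.q_start, top.q_end) == (0, 1000)
        assert top.identities == 1000
        assert top.s_strand == "+"

    def test_reverse_complement_hit_on_minus_strand(self):
        seq = random_dna(800, 2)
        hsps = align_pair(seq, reverse_complement(seq))
        top = hsps[0]
        assert top.s_strand == "-"
        assert (top.q_start, top.q_end) == (0, 800)
        assert (top.s_start, top.s_end) == (0, 800)
        assert top.identities == 800

    def test_unrelated_random_pairs_rarely_align(self):
        hits = sum(
            bool(align_pair(random_dna(200, 2 * s + 1), random_dna(200, 2 * s + 2)))
            for s in range(100)
        )
        assert hits <= 5

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            align_pair("", "ACGT")

    def test_invalid_gap_penalties_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            align_pair("ACGT" * 30, "ACGT" * 30, ScoringParams(gap_open=0))

    def test_n_never_counts_as_identity(self):
        seq = random_dna(200, 3)
        noisy = seq[:50] + "N" * 10 + seq[60:]
        hsps = align_pair(seq, noisy)
        _, ident = merge_hsps(hsps, "query", 200)
        assert ident <= 190

    @pytest.mark.parametrize("seed", range(10))
    def test_merged_identities_match_smith_waterman_oracle(self, seed):
        """On short substitution-diverged pairs the merged identity count
        agrees with exhaustive Smith-Waterman within +-2."""
        ancestor = random_dna(180, 100 + seed)
        a = mutate(ancestor, 0.04, 200 + seed)
        b = mutate(ancestor, 0.04, 300 + seed)
        merged_len, ident = merge_hsps(align_pair(a, b), "query", len(a))
        oracle = sw_nt_identities(a, b)
        assert abs(ident - oracle) <= 2


class TestMergeHsps:
    def _hsp(self, qs, qe, ident, score):
        return AlignmentHSP(qs, qe, qs, qe, "+", ident, qe - qs, score)

    def test_overlap_trimming_rule(self):
        hsps = [self._hsp(0, 100, 100, 200), self._hsp(50, 150, 100, 200)]
        aligned, ident = merge_hsps(hsps, "query")
        assert (aligned, ident) == (150, 150)

    def test_disjoint_hsps_simply_add(self):
        hsps = [self._hsp(0, 100, 90, 180), self._hsp(200, 300, 90, 180)]
        assert merge_hsps(hsps, "query") == (200, 180)

    def test_empty_list(self):
        assert merge_hsps([], "query") == (0, 0)

    def test_higher_score_kept_intact(self):
        hsps = [self._hsp(0, 100, 80, 100), self._hsp(50, 150, 100, 200)]
        aligned, ident = merge_hsps(hsps, "query")
        # the 200-score HSP survives whole; the other is trimmed to [0,50)
        assert aligned == 150
        assert ident == 100 + (80 * 50) // 100

    def test_coordinates_beyond_sequence_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            merge_hsps([self._hsp(0, 100, 90, 100)], "query", seq_len=50)

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 400),
                st.integers(1, 150),
                st.integers(1, 300),
            ),
            min_size=0,
            max_size=12,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_merge_invariants(self, raw):
        hsps = [
            AlignmentHSP(s, s + ln, s, s + ln, "+", max(1, ln // 2), ln, sc)
            for s, ln, sc in raw
        ]
        aligned, ident = merge_hsps(hsps, "query", seq_len=600)
        assert 0 <= ident <= aligned <= 600
        # input order must not matter
        assert merge_hsps(list(reversed(hsps)), "query", 600) == (aligned, ident)


class TestIntergenomicSimilarity:
    def test_identical_genomes(self):
        g = GenomeRecord("a", "a", random_dna(2000, 4))
        h = GenomeRecord("b", "b", g.sequence)
        s = intergenomic_similarity(g, h)
        assert s.sim_percent == pytest.approx(100.0, abs=1e-9)
        assert s.aligned_frac_a == pytest.approx(1.0)
        assert s.aligned_frac_b == pytest.approx(1.0)

    def test_half_shared_genome_pair(self):
        a = random_dna(1000, 11)
        b = a[:500] + random_dna(500, 12)
        s = intergenomic_similarity(GenomeRecord("a", "a", a), GenomeRecord("b", "b", b))
        assert s.sim_percent == pytest.approx(50.0, abs=2.0)
        # numerator cross-check against the exhaustive local-alignment oracle
        assert abs(s.id_ab - sw_nt_identities(a, b)) <= 10

    def test_symmetry(self):
        gs, _ = sd.simulate_population(
            sd.PopulationConfig(
                n_clusters=1, genera_per_cluster=1, genomes_per_genus=2,
                n_singletons=0, rng_seed=8,
            )
        )
        ab = intergenomic_similarity(gs[0], gs[1]).sim_percent
        ba = intergenomic_similarity(gs[1], gs[0]).sim_percent
        assert ab == pytest.approx(ba, abs=1e-9)


class TestSimilarityMatrix:
    def test_identical_genomes_all_100(self):
        seq = random_dna(1500, 5)
        gs = [GenomeRecord(f"g{i}", "g", seq) for i in range(3)]
        mat = similarity_matrix(gs)
        assert np.allclose(mat.values, 100.0)

    def test_unrelated_genomes_near_zero(self):
        gs = [
            GenomeRecord("a", "a", random_dna(10000, 21)),
            GenomeRecord("b", "b", random_dna(10000, 22)),
        ]
        mat = similarity_matrix(gs)
        assert mat.iloc[0, 1] < 5

    def test_matrix_equals_transpose(self, demo_results):
        mat = demo_results["sim"]
        assert (mat.values == mat.values.T).all()
        assert np.allclose(np.diag(mat.values), 100.0)

    def test_fewer_than_two_genomes_rejected(self):
        with pytest.raises(ValueError, match="2 genomes"):
            similarity_matrix([GenomeRecord("a", "a", "ACGT" * 100)])


def test_divergence_monotonicity():
    """Mean similarity decreases as the planted substitution rate grows."""
    means = []
    for d in (0.02, 0.08):
        sims = []
        for seed in range(10):
            gs, _ = sd.simulate_population(
                sd.PopulationConfig(
                    n_clusters=1, genera_per_cluster=1, genomes_per_genus=2,
                    intra_genus_divergence=d, private_genes_per_genome=0,
                    n_singletons=0, rng_seed=7000 + seed,
                )
            )
            sims.append(intergenomic_similarity(gs[0], gs[1]).sim_percent)
        means.append(np.mean(sims))
    assert means[0] > means[1]


def test_backend_equivalence_internal_vs_blastn():
    """The built-in aligner and the external blastn wrapper agree on
    sim_percent within +-2 points."""
    gs, _ = sd.simulate_population(
        sd.PopulationConfig(
            n_clusters=1, genera_per_cluster=2, genomes_per_genus=2,
            n_singletons=0, rng_seed=5,
        )
    )
    for i, j in [(0, 1), (0, 2)]:
        internal = intergenomic_similarity(gs[i], gs[j]).sim_percent
        external = intergenomic_similarity(gs[i], gs[j], backend="blastn").sim_percent
        assert internal == pytest.approx(external, abs=2.0)


def test_divergence_estimator_round_trip():
    for d in (0.01, 0.05, 0.2):
        ident = sd.expected_pair_identity(d)
        assert divergence_from_identity(ident) == pytest.approx(d, rel=1e-6)


def test_pairwise_identity_accessor():
    g = GenomeRecord("a", "a", random_dna(1000, 30))
    h = GenomeRecord("b", "b", g.sequence)
    s = intergenomic_similarity(g, h)
    assert pairwise_identity(s, 1000, 1000) == pytest.approx(1.0)
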