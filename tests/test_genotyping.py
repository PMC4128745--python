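"""In silico digestion, band matching, neighbor joining, genome summaries."""

import io as _stdio
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from charkit import simulate as sim
from conftest import random_additive_matrix
from charkit.errors import InvalidInputError
from charkit.genotyping import (
    DistanceMatrix,
    Fingerprint,
    GenomeRecord,
    anticodon_to_codon,
    codon_usage_compare,
    digest,
    distance_matrix,
    fingerprint_similarity,
    genome_stats,
    neighbor_joining,
)


class TestDigest:
    def test_manual_enumeration(self):
        fp = digest(GenomeRecord("g", "GCGCAAGCGC"))
        assert sorted(fp.fragment_lengths) == [1, 3, 6]

    def test_absent_motif_gives_full_length_fragment(self):
        fp = digest(GenomeRecord("g", "AATTAATT"))
        assert fp.fragment_lengths == (8,)

    def test_overlapping_sites_both_cut(self):
        # GCGCGC contains GCGC at offsets 0 and 2
        fp = digest(GenomeRecord("g", "GCGCGCAA"))
        assert sorted(fp.fragment_lengths) == [2, 3, 3]

    def test_circular_topology_counts_cuts(self):
        lin = digest(GenomeRecord("g", "AAGCGCTTGCGCTT"))
        circ = digest(GenomeRecord("g", "AAGCGCTTGCGCTT", topology="circular"))
        assert len(lin.fragment_lengths) == 3
        assert len(circ.fragment_lengths) == 2
        assert sum(circ.fragment_lengths) == 14

    def test_n_in_window_skips_site(self):
        fp = digest(GenomeRecord("g", "GCNCAAGCGC"))
        assert sorted(fp.fragment_lengths) == [1, 9]

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            GenomeRecord("g", "")
        with pytest.raises(InvalidInputError):
            digest(GenomeRecord("g", "ACGT"), site="")
        with pytest.raises(InvalidInputError):
            digest(GenomeRecord("g", "ACGT"), cut_offset=9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_fragment_conservation_on_random_genomes(self, seed):
        (g,) = sim.simulate_genomes(1, length=5000, gc=0.5, seed=seed)
        fp = digest(g)
        assert sum(fp.fragment_lengths) == len(g)


class TestSimilarity:
    def test_self_similarity_is_one(self):
        fp = Fingerprint("g", "HhaI", (100, 250, 700))
        assert fingerprint_similarity(fp, fp) == 1.0

    def test_half_overlap_dice(self):
        a = Fingerprint("a", "HhaI", (100, 200))
        b = Fingerprint("b", "HhaI", (100, 300))
        assert fingerprint_similarity(a, b) == 0.5

    def test_tolerance_boundary(self):
        a = Fingerprint("a", "HhaI", (100,))
        b = Fingerprint("b", "HhaI", (101,))
        assert fingerprint_similarity(a, b, tolerance_bp=1) == 1.0
        assert fingerprint_similarity(a, b, tolerance_bp=0) == 0.0

    def test_noise_floor_discards_short_fragments(self):
        a = Fingerprint("a", "HhaI", (1000, 30))  # 30 < 5% of 1000
        b = Fingerprint("b", "HhaI", (1000,))
        assert fingerprint_similarity(a, b) == 1.0

    def test_enzyme_mismatch_rejected(self):
        a = Fingerprint("a", "HhaI", (100,))
        b = Fingerprint("b", "EcoRI", (100,))
        with pytest.raises(InvalidInputError):
            fingerprint_similarity(a, b)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        a = Fingerprint("a", "HhaI", tuple(rng.integers(20, 2000, size=8)))
        b = Fingerprint("b", "HhaI", tuple(rng.integers(20, 2000, size=5)))
        sab = fingerprint_similarity(a, b)
        sba = fingerprint_similarity(b, a)
        assert sab == sba
        assert 0.0 <= sab <= 1.0


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float),
        )
        assert neighbor_joining(dm) == "(A:1,B:1,C:3);"

    def test_equal_distances_resolve_deterministically(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(list("ABCD"), d)
        t1 = neighbor_joining(dm)
        t2 = neighbor_joining(dm)
        assert t1 == t2  # tie-break by label order is deterministic

    def test_trivial_trees_below_three_taxa(self):
        assert neighbor_joining(DistanceMatrix(["A"], np.zeros((1, 1)))) \
            == "(A:0);"
        two = DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert neighbor_joining(two) == "(A:0.5,B:0.5);"

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(InvalidInputError):
            DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    @pytest.mark.parametrize("n", [4, 5])
    def test_recovers_topology_of_additive_matrices(self, n, rng):
        import skbio

        for _ in range(10):
            labels, d, true_tree = random_additive_matrix(n, rng)
            newick = neighbor_joining(DistanceMatrix(labels, d))
            ours = skbio.TreeNode.read(_stdio.StringIO(newick))
            assert true_tree.compare_rfd(ours) == 0.0

    @pytest.mark.parametrize("n", [5, 7])
    def test_agrees_with_reference_nj_on_random_matrices(self, n, rng):
        # independent implementation cross-check on non-additive matrices
        import skbio
        from skbio.tree import nj as skbio_nj

        for _ in range(5):
            d = rng.uniform(0.1, 1.0, size=(n, n))
            d = (d + d.T) / 2.0
            np.fill_diagonal(d, 0.0)
            labels = [chr(ord("A") + i) for i in range(n)]
            ours = skbio.TreeNode.read(
                _stdio.StringIO(neighbor_joining(DistanceMatrix(labels, d)))
            )
            theirs = skbio_nj(skbio.DistanceMatrix(d, labels))
            assert theirs.compare_rfd(ours) == 0.0


class TestCloneClustering:
    def test_clone_near_parent_unrelated_far(self):
        genomes = sim.simulate_genomes(
            3, length=10_000, gc=0.5, clone_edits=[(0, 500)], seed=7
        )
        fps = [digest(g) for g in genomes]
        dm = distance_matrix(fps)
        idx = {label: i for i, label in enumerate(dm.labels)}
        d_clone = dm.values[idx["G000"], idx["G000_clone500"]]
        assert d_clone < 0.3
        for other in ("G001", "G002"):
            assert dm.values[idx["G000"], idx[other]] > 0.7

    def test_insertion_changes_at_most_two_bands(self):
        for seed in range(5):
            parent, clone = sim.simulate_genomes(
                1, length=10_000, clone_edits=[(0, 500)], seed=seed
            )
            fa = Counter(digest(parent).fragment_lengths)
            fb = Counter(digest(clone).fragment_lengths)
            assert sum(((fa - fb) + (fb - fa)).values()) <= 2


class TestGenomeStats:
    def test_gc_extremes(self):
        assert genome_stats(GenomeRecord("g", "GGCC"))["gc_percent"] == 100.0
        assert genome_stats(GenomeRecord("g", "ATAT"))["gc_percent"] == 0.0

    def test_n_excluded_from_gc_denominator(self):
        stats = genome_stats(GenomeRecord("g", "GCNNAT"))
        assert stats["gc_percent"] == pytest.approx(50.0)
        assert stats["length_bp"] == 6

    def test_coding_percent_union_of_intervals(self):
        g = GenomeRecord("g", "A" * 100)
        stats = genome_stats(g, [(1, 30), (21, 50)])  # union covers 1..50
        assert stats["coding_percent"] == pytest.approx(50.0)

    def test_out_of_bounds_interval(self):
        with pytest.raises(InvalidInputError):
            genome_stats(GenomeRecord("g", "ACGT"), [(1, 10)])


class TestCodonUsage:
    def test_single_codon_cds(self):
        out = codon_usage_compare(["ATGATG"], {}, ["CAU"])
        assert out["phage_table"]["ATG"] == 1000.0
        assert out["matched_codons"][0]["codon"] == "ATG"

    def test_anticodon_reverse_complement(self):
        assert anticodon_to_codon("CAU") == "ATG"
        assert anticodon_to_codon("GAA") == "TTC"

    def test_partial_codon_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="divisible by 3"):
            out = codon_usage_compare(["ATGAT"], {}, ["CAU"])
        assert sum(out["phage_table"].values()) == pytest.approx(1000.0)

    def test_enriched_codons_flagged_against_host_table(self):
        # construct CDS enriching 16 of 21 matched codons above the host
        codons = [
            "".join(c) for c in
            [(a, b, d) for a in "ACGT" for b in "ACGT" for d in "ACGT"]
        ][:21]
        host = {c: 10.0 for c in codons}
        enriched = codons[:16]
        cds = "".join(enriched * 10) + "".join(codons[16:])
        anticodons = [anticodon_to_codon(c) for c in codons]  # involution
        out = codon_usage_compare([cds], host, anticodons)
        assert out["n_matched"] == 21
        assert out["n_higher_in_phage"] == 16

    def test_empty_cds_rejected(self):
        with pytest.raises(InvalidInputError):
            codon_usage_compare([], {}, [])
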