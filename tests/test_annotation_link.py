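"""Upstream windows, gene association, local alignment, allele search."""

import numpy as np
import pytest
from Bio import Align

from sagetag.io_formats import GeneModel, SequenceRecord, reverse_complement
from sagetag.annotation_link import (
    DEFAULT_SCORING,
    extract_upstream,
    find_x_allele,
    genes_within_upstream,
    local_align,
    upstream_window,
)
from sagetag.reference_mapping import ReferenceSet, TagHit


def hit(start, strand="+", seq_id="X_0", partition="X", tag="A" * 26):
    return TagHit(tag, partition, seq_id, start, strand)


class TestUpstreamWindow:
    def test_plus_strand_window_is_left_of_anchor(self):
        w = upstream_window(hit(5000), 2000, ref_length=10000)
        assert (w.start, w.end, w.truncated) == (3000, 5000, False)

    def test_plus_strand_truncates_at_origin(self):
        w = upstream_window(hit(500), 2000, ref_length=10000)
        assert (w.start, w.end, w.truncated) == (0, 500, True)

    def test_minus_strand_window_is_right_of_tag(self):
        w = upstream_window(hit(1000, "-"), 1000, ref_length=10000)
        assert (w.start, w.end, w.truncated) == (1026, 2026, False)

    def test_minus_strand_truncates_at_end(self):
        w = upstream_window(hit(9900, "-"), 1000, ref_length=10000)
        assert (w.start, w.end, w.truncated) == (9926, 10000, True)

    def test_out_of_bounds_hit_rejected(self):
        with pytest.raises(ValueError):
            upstream_window(hit(9990), 100, ref_length=10000)


class TestGenesWithinUpstream:
    genes = [
        GeneModel("inside", "X_0", 4400, 4900, "+"),
        GeneModel("too_far", "X_0", 1000, 1800, "+"),
        GeneModel("straddle", "X_0", 2900, 3100, "+"),
        GeneModel("other_seq", "Y_0", 4400, 4900, "+"),
    ]

    def test_any_overlap_rule(self):
        got = genes_within_upstream(hit(5000), self.genes, 2000, ref_length=10000)
        assert set(got) == {"inside", "straddle"}

    def test_sorted_by_proximity_to_anchor(self):
        got = genes_within_upstream(hit(5000), self.genes, 2000, ref_length=10000)
        assert got == ["inside", "straddle"]

    def test_widening_never_removes_genes(self):
        narrow = set(genes_within_upstream(hit(5000), self.genes, 1000))
        wide = set(genes_within_upstream(hit(5000), self.genes, 4000))
        assert narrow <= wide

    def test_unstranded_window_covers_both_flanks(self):
        down = [GeneModel("downstream", "X_0", 5100, 5400, "+")]
        assert genes_within_upstream(hit(5000), down, 2000) == []
        assert genes_within_upstream(hit(5000), down, 2000, stranded=False) == [
            "downstream"
        ]


class TestExtractUpstream:
    def make_refs(self, seq):
        return ReferenceSet({"X": [SequenceRecord("X_0", seq)]})

    def test_plus_strand_forward_substring(self):
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        refs = self.make_refs(seq)
        rec, truncated = extract_upstream(hit(300), refs, 100)
        assert rec.sequence == seq[200:300] and not truncated

    def test_minus_strand_reverse_complement(self):
        rng = np.random.default_rng(1)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        refs = self.make_refs(seq)
        rec, _ = extract_upstream(hit(100, "-"), refs, 100)
        assert rec.sequence == reverse_complement(seq[126:226])

    def test_hit_at_origin_gives_flagged_empty(self):
        refs = self.make_refs("A" * 100)
        rec, truncated = extract_upstream(hit(0), refs, 50)
        assert rec.sequence == "" and truncated

    def test_strand_consistency_under_global_reverse_complement(self):
        """Flipping the whole reference and the hit strand leaves the
        extracted upstream sequence unchanged."""
        rng = np.random.default_rng(2)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])
        refs = self.make_refs(seq)
        p = 230
        fwd, _ = extract_upstream(hit(p), refs, 80)
        flipped = self.make_refs(reverse_complement(seq))
        p_flipped = len(seq) - 26 - p
        rev, _ = extract_upstream(hit(p_flipped, "-"), flipped, 80)
        assert fwd.sequence == rev.sequence


def oracle_best_local_score(q, t, match=2, mismatch=-1, gap=-2):
    """Exhaustive enumeration of every local alignment path."""
    best = 0
    n, m = len(q), len(t)

    def step(i, j, score):
        nonlocal best
        if score > best:
            best = score
        if i < n and j < m:
            s = match if (q[i] == t[j] and q[i] != "N") else mismatch
            step(i + 1, j + 1, score + s)
        if i < n:
            step(i + 1, j, score + gap)
        if j < m:
            step(i, j + 1, score + gap)

    for i in range(n):
        for j in range(m):
            step(i, j, 0)
    return best


def biopython_local_score(q, t):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = DEFAULT_SCORING["match"]
    aligner.mismatch_score = DEFAULT_SCORING["mismatch"]
    aligner.open_gap_score = DEFAULT_SCORING["gap_open"]
    aligner.extend_gap_score = DEFAULT_SCORING["gap_extend"]
    return int(aligner.score(q, t))


class TestLocalAlign:
    def test_perfect_self_alignment(self):
        r = local_align("ACGTACGT", "ACGTACGT")
        assert (r.score, r.identity) == (16, 1.0)
        assert r.query_span == (0, 8) and r.target_span == (0, 8)

    def test_no_positive_cell(self):
        r = local_align("AAAA", "CCCC")
        assert r.score == 0 and r.n_columns == 0

    def test_empty_inputs(self):
        assert local_align("", "ACGT").score == 0
        assert local_align("ACGT", "").score == 0

    def test_N_never_matches(self):
        assert local_align("ANA", "ANA").score < 6
        assert local_align("AAA", "AAA").score == 6

    def test_matches_exhaustive_oracle_on_small_pair(self):
        assert local_align("ACGT", "ACGGT").score == oracle_best_local_score(
            "ACGT", "ACGGT"
        )

    def test_score_symmetry_and_revcomp_invariance(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        for _ in range(20):
            q = "".join(bases[rng.integers(0, 4, int(rng.integers(5, 30)))])
            t = "".join(bases[rng.integers(0, 4, int(rng.integers(5, 30)))])
            s = local_align(q, t).score
            assert local_align(t, q).score == s
            assert (
                local_align(reverse_complement(q), reverse_complement(t)).score == s
            )

    def test_agrees_with_biopython_on_random_pairs(self):
        rng = np.random.default_rng(6)
        bases = np.array(list("ACGT"))
        for _ in range(50):
            q = "".join(bases[rng.integers(0, 4, int(rng.integers(1, 60)))])
            t = "".join(bases[rng.integers(0, 4, int(rng.integers(1, 60)))])
            assert local_align(q, t).score == biopython_local_score(q, t)

    def test_affine_gap_costs_rejected(self):
        with pytest.raises(ValueError):
            local_align("ACGT", "ACGT", {"gap_open": -5, "gap_extend": -1})


class TestFindXAllele:
    def test_simulated_allele_recovery(self, small_sim):
        """Planted X copies above the identity cutoff are reported; the
        heavily mutated copy is not."""
        sim = small_sim
        found = {}
        for pair in sim.truth.allele_pairs:
            p = sim.truth.planted[pair.yh_label]
            yh_hit = TagHit(p.tag, *p.positions[0])
            results = find_x_allele(yh_hit, sim.refs)
            found[pair.yh_label] = (pair.realized_identity, results)
        for label, (identity, results) in found.items():
            if identity > 0.85:
                assert results, f"{label}: allele copy at identity {identity} missed"
                assert results[0].identity > 0.80
            elif identity < 0.75:
                assert not results, f"{label}: divergent copy wrongly reported"

    def test_no_homolog_gives_empty_list(self):
        rng = np.random.default_rng(9)
        bases = np.array(list("ACGT"))
        x = "".join(bases[rng.integers(0, 4, 3000)])
        yh = "".join(bases[rng.integers(0, 4, 3000)])
        refs = ReferenceSet(
            {"X": [SequenceRecord("X_0", x)], "Yh": [SequenceRecord("Yh_0", yh)]}
        )
        yh_hit = TagHit("A" * 26, "Yh", "Yh_0", 2000, "+")
        assert find_x_allele(yh_hit, refs, upstream_length=500) == []

    def test_requires_yh_hit(self):
        with pytest.raises(ValueError):
            find_x_allele(hit(100, partition="X"), ReferenceSet({"X": []}))
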