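"""Consensus rule, flank extraction, Smith-Waterman, annotation criterion."""

import numpy as np
import pytest

from radpop.align import smith_waterman
from radpop.consensus import (
    annotate_outlier,
    consensus_outliers,
    extract_flank_window,
    revcomp,
)
from radpop.core import LocusInfo
from radpop.synthetic import (
    SimConfig,
    emit_reference_and_transcriptome,
    simulate_dataset,
)


class TestConsensus:
    def test_set_intersection(self):
        assert consensus_outliers({"a", "b", "c"}, {"b", "c", "d"}) == {"b", "c"}

    def test_subset_gives_smaller_set(self):
        small, big = {"x", "y"}, {"x", "y", "z", "w"}
        assert consensus_outliers(small, big) == small

    def test_disjoint_empty(self):
        assert consensus_outliers({"a"}, {"b"}) == set()

    def test_commutative_and_idempotent(self):
        a, b = {"p", "q"}, {"q", "r"}
        assert consensus_outliers(a, b) == consensus_outliers(b, a)
        shared = consensus_outliers(a, b)
        assert consensus_outliers(shared, shared) == shared

    def test_mapping_universe_mismatch_is_error(self):
        with pytest.raises(ValueError, match="universe"):
            consensus_outliers({"a": True}, {"b": True})


def _locus(contig, pos):
    return LocusInfo(f"{contig}_{pos}", contig, pos, "t", "A", "G")


class TestFlankWindow:
    def test_centered_window(self):
        ref = {"c": "A" * 1000}
        seq, off = extract_flank_window(ref, _locus("c", 100))
        assert len(seq) == 80 and off == 40

    def test_clipped_at_contig_start(self):
        ref = {"c": "A" * 1000}
        seq, off = extract_flank_window(ref, _locus("c", 10))
        assert len(seq) == 49 and off == 9

    def test_single_tag_width(self):
        ref = {"c": "A" * 200}
        seq, off = extract_flank_window(ref, _locus("c", 100), width=36)
        assert len(seq) == 36 and off == 18

    def test_absent_contig_is_error(self):
        with pytest.raises(KeyError):
            extract_flank_window({"other": "AAAA"}, _locus("c", 2))

    def test_position_outside_contig_is_error(self):
        with pytest.raises(ValueError, match="outside"):
            extract_flank_window({"c": "AAAA"}, _locus("c", 10))


def brute_force_local_score(q, s, match=1.0, mismatch=-2.0,
                            gap_open=-2.0, gap_extend=-1.0):
    """Exhaustive enumeration of every local alignment of q vs s.

    Recursion over (i, j, in_gap_state) from every start cell; exponential,
    so only for tiny strings."""
    best = 0.0

    def extend(i, j, score, state):
        nonlocal best
        best = max(best, score)
        if i < len(q) and j < len(s):
            sub = match if (q[i] == s[j] and q[i] != "N") else mismatch
            extend(i + 1, j + 1, score + sub, "M")
        if j < len(s):
            cost = gap_extend if state == "E" else gap_open
            extend(i, j + 1, score + cost, "E")
        if i < len(q):
            cost = gap_extend if state == "F" else gap_open
            extend(i + 1, j, score + cost, "F")

    for i in range(len(q)):
        for j in range(len(s)):
            sub = match if (q[i] == s[j] and q[i] != "N") else mismatch
            extend(i + 1, j + 1, sub, "M")
    return best


class TestSmithWaterman:
    def test_identical_30mers(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=30))
        aln = smith_waterman(seq, seq)
        assert aln.identity == 1.0 and aln.n_columns == 30
        assert aln.score == 30.0

    def test_one_mismatch_identity(self):
        # a 37-column alignment with 36 matches -> identity 36/37
        seq = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTA"
        mutated = seq[:18] + "C" + seq[19:]
        aln = smith_waterman(seq, mutated)
        assert aln.n_columns == 37 and aln.n_matches == 36
        assert aln.identity == pytest.approx(36 / 37)

    def test_empty_sequence(self):
        assert smith_waterman("", "ACGT") is None

    def test_matches_brute_force_enumeration(self):
        """DP score equals exhaustive enumeration of all local alignments
        on random 6-mers."""
        rng = np.random.default_rng(6)
        for _ in range(25):
            q = "".join(rng.choice(list("ACGT"), size=6))
            s = "".join(rng.choice(list("ACGT"), size=6))
            aln = smith_waterman(q, s)
            score = aln.score if aln else 0.0
            assert score == pytest.approx(brute_force_local_score(q, s))

    def test_matches_biopython_on_10mers(self):
        """Independent cross-check: Biopython's PairwiseAligner local score
        under the same affine scheme, 200 random pairs."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 1
        aligner.mismatch_score = -2
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -1
        rng = np.random.default_rng(7)
        for _ in range(200):
            q = "".join(rng.choice(list("ACGT"), size=10))
            s = "".join(rng.choice(list("ACGT"), size=10))
            aln = smith_waterman(q, s)
            mine = aln.score if aln else 0.0
            assert mine == pytest.approx(max(aligner.score(q, s), 0.0))


class TestAnnotation:
    def _window_in_transcript(self, n=40, seed=8):
        rng = np.random.default_rng(seed)
        window = "".join(rng.choice(list("ACGT"), size=n))
        flank = "".join(rng.choice(list("ACGT"), size=25))
        return window, {"tx1": flank + window + flank}

    def test_perfect_embedded_match_positive(self):
        window, tx = self._window_in_transcript(40)
        hits = annotate_outlier(window, 20, tx, locus_id="l1")
        assert hits and hits[0].positive

    def test_short_match_negative(self):
        # perfect 24-bp match fails the >=25 bp length criterion
        window, tx = self._window_in_transcript(24)
        hits = annotate_outlier(window, 12, tx)
        assert hits and not hits[0].positive

    def test_low_identity_negative(self):
        rng = np.random.default_rng(9)
        window = "".join(rng.choice(list("ACGT"), size=30))
        # mutate ~15% of the embedded copy -> identity below 0.90
        seq = list(window)
        for i in range(0, 30, 7):
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        tx = {"tx1": "".join(seq)}
        hits = annotate_outlier(window, 15, tx)
        assert all(not h.positive for h in hits)

    def test_block_must_span_snp(self):
        rng = np.random.default_rng(10)
        left = "".join(rng.choice(list("ACGT"), size=30))
        right = "".join(rng.choice(list("ACGT"), size=30))
        window = left + right
        tx = {"tx1": left}  # only the left half matches
        hits = annotate_outlier(window, 45, tx)  # SNP in the unmatched half
        assert all(not h.positive for h in hits)

    def test_reverse_complement_detected(self):
        window, tx = self._window_in_transcript(40)
        tx_rc = {"tx1": revcomp(tx["tx1"])}
        hits = annotate_outlier(window, 20, tx_rc)
        assert hits and hits[0].positive and hits[0].strand == "-"

    def test_empty_transcriptome(self):
        assert annotate_outlier("ACGTACGT", 4, {}) == []


def test_planted_annotation_recovered_exactly():
    """On a synthetic reference/transcriptome pair the positive set equals
    the planted set (identity 1.0, length >= 40)."""
    from conftest import make_gm

    # loci spaced 200 bp apart so flanking windows never overlap
    gm = make_gm(np.zeros((2, 30), dtype=np.int8),
                 positions=[1 + 200 * j for j in range(30)])
    planted = [gm.loci[j].locus_id for j in (2, 7, 11)]
    contigs, tx, expected = emit_reference_and_transcriptome(
        gm, planted, seed=13, planted_identity=1.0
    )
    assert expected == planted
    by_id = {l.locus_id: l for l in gm.loci}
    positives = []
    for locus in gm.loci:
        window, off = extract_flank_window(contigs, by_id[locus.locus_id])
        hits = annotate_outlier(window, off, tx, locus_id=locus.locus_id)
        if any(h.positive for h in hits):
            positives.append(locus.locus_id)
    assert positives == planted


def test_degraded_planted_identity_negative():
    cfg = SimConfig(seed=92, n_pops=1, samples_per_pop=4, n_loci=10,
                    replicates_per_pop=0)
    gm, _, _ = simulate_dataset(cfg)
    planted = [gm.loci[3].locus_id]
    contigs, tx, expected = emit_reference_and_transcriptome(
        gm, planted, seed=14, planted_identity=0.80
    )
    assert expected == []
    locus = gm.loci[3]
    window, off = extract_flank_window(contigs, locus)
    hits = annotate_outlier(window, off, tx, locus_id=locus.locus_id)
    assert all(not h.positive for h in hits)
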