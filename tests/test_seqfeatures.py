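import numpy as np
import pytest

from cardiomembrane.seqfeatures import (
    KYTE_DOOLITTLE,
    has_tm,
    hydropathy_profile,
    pairwise_percent_identity,
    predict_tm_segments,
)
from cardiomembrane.types import ValidationError


def brute_force_tm(seq, window=19, threshold=1.6, min_len=15, merge_gap=3):
    """Independent oracle: explicit window scan + run merging."""
    scores = [KYTE_DOOLITTLE.get(c, 0.0) for c in seq.upper()]
    n = len(scores)
    if n < window:
        return []
    above = []
    for start in range(n - window + 1):
        mean = sum(scores[start : start + window]) / window
        above.append(mean > threshold)
    spans = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            spans.append((start, i - 1 + window - 1))
            start = None
    if start is not None:
        spans.append((start, len(above) - 1 + window - 1))
    merged = []
    for s, e in spans:
        if merged and s - merged[-1][1] - 1 <= merge_gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return [(s + 1, e + 1) for s, e in merged if e - s + 1 >= min_len]


def brute_force_identity(a, b, match=1.0, mismatch=0.0, gap=-1.0):
    """Exhaustive enumeration of every global alignment.

    Returns (best score, set of identity percentages achieved by the
    co-optimal alignments) — any deterministic tie-break must land in that
    set.
    """
    outcomes = []

    def rec(i, j, score, cols, matches):
        if i == len(a) and j == len(b):
            outcomes.append((score, cols, matches))
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s, cols + 1, matches + (a[i] == b[j]))
        if i < len(a):
            rec(i + 1, j, score + gap, cols + 1, matches)
        if j < len(b):
            rec(i, j + 1, score + gap, cols + 1, matches)

    rec(0, 0, 0.0, 0, 0)
    best = max(s for s, _, _ in outcomes)
    identities = {
        round(100.0 * m / c, 9) for s, c, m in outcomes if s == pytest.approx(best)
    }
    return best, identities


class TestPredictTm:
    def test_polyserine_has_no_segments(self):
        assert predict_tm_segments("S" * 60) == []

    def test_single_leucine_core(self):
        seq = "S" * 30 + "L" * 25 + "S" * 30
        segs = predict_tm_segments(seq)
        assert len(segs) == 1
        seg = segs[0]
        # the hydrophobic core (residues 31..55) lies inside the call
        assert seg.start <= 31 and seg.end >= 55
        assert seg.mean_hydropathy > 0

    def test_two_separated_stretches(self):
        seq = "S" * 25 + "L" * 22 + "S" * 40 + "V" * 22 + "S" * 25
        segs = predict_tm_segments(seq)
        assert len(segs) == 2
        assert segs[0].end < segs[1].start

    def test_short_sequence_warns_empty(self):
        with pytest.warns(UserWarning):
            assert predict_tm_segments("LLLV") == []

    def test_matches_brute_force_oracle_on_random_sequences(self, rng):
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(40):
            n = int(rng.integers(19, 200))
            seq = "".join(rng.choice(alphabet, size=n))
            got = [(s.start, s.end) for s in predict_tm_segments(seq)]
            assert got == brute_force_tm(seq)

    def test_segments_sorted_disjoint_within_bounds(self, rng):
        seq = "".join(
            rng.choice(list("LIVFASTNQDEKRGP"), size=300)
        )
        segs = predict_tm_segments(seq)
        last_end = 0
        for s in segs:
            assert 1 <= s.start <= s.end <= len(seq)
            assert s.start > last_end
            assert s.length >= 15
            last_end = s.end

    def test_palindromic_profile_mirrors_segments(self):
        half = "S" * 20 + "L" * 22 + "S" * 10
        seq = half + half[::-1]
        segs = predict_tm_segments(seq)
        n = len(seq)
        mirrored = sorted((n - s.end + 1, n - s.start + 1) for s in segs)
        assert mirrored == [(s.start, s.end) for s in segs]

    def test_window_profile_length(self):
        prof = hydropathy_profile("A" * 30, window=19)
        assert len(prof) == 12
        assert np.allclose(prof, 1.8)


class TestHasTm:
    def test_predicted_segment(self):
        seqs = {"H1": "S" * 30 + "L" * 25 + "S" * 30}
        assert has_tm(seqs, ["H1"])

    def test_ingested_annotation_without_sequence(self):
        assert has_tm(None, ["H1"], ingested_tm={"H1": 2})

    def test_neither_source(self):
        assert not has_tm({"H1": "S" * 60}, ["H1"], ingested_tm={})


class TestPercentIdentity:
    def test_identical(self):
        assert pairwise_percent_identity("MKLV", "MKLV") == 100.0

    def test_fully_distinct(self):
        assert pairwise_percent_identity("AAAA", "CCCC") == 0.0

    def test_against_exhaustive_enumeration(self):
        for a, b in [("ACGTAC", "ACTAC"), ("MKLVAA", "MKIV"), ("AC", "CA"),
                     ("PEPTIDE", "PEPTIDE"[::-1])]:
            _, identities = brute_force_identity(a, b)
            got = pairwise_percent_identity(a, b)
            assert any(got == pytest.approx(i) for i in identities)

    def test_optimal_score_matches_biopython(self, rng):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = 0
        aligner.open_gap_score = -1
        aligner.extend_gap_score = -1
        from cardiomembrane.seqfeatures import _needleman_wunsch

        alphabet = list("ACDEFGHIKL")
        for _ in range(20):
            a = "".join(rng.choice(alphabet, size=int(rng.integers(3, 12))))
            b = "".join(rng.choice(alphabet, size=int(rng.integers(3, 12))))
            aln_a, aln_b = _needleman_wunsch(a, b, 1.0, 0.0, -1.0)
            score = sum(
                1.0 if (x == y and x != "-") else (-1.0 if "-" in (x, y) else 0.0)
                for x, y in zip(aln_a, aln_b)
            )
            assert score == pytest.approx(aligner.score(a, b))

    def test_symmetry(self, rng):
        alphabet = list("ACDEFG")
        for _ in range(10):
            a = "".join(rng.choice(alphabet, size=6))
            b = "".join(rng.choice(alphabet, size=8))
            assert pairwise_percent_identity(a, b) == pytest.approx(
                pairwise_percent_identity(b, a)
            )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_percent_identity("", "ACGT")
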