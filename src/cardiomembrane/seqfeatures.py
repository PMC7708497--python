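"""Transmembrane-segment prediction and cross-species sequence conservation.

TM segments are called with the classic Kyte–Doolittle sliding-window
heuristic (window 19, GRAVY threshold 1.6, minimum segment length 15):
window means above the threshold mark candidate centers, runs of centers are
expanded to the window extent, near-adjacent runs are merged.  This is a
transparent stand-in for full HMM topology predictors; externally computed
TM calls (e.g. TMHMM output) can be ingested instead and take the same
downstream path.

Conservation is reported as global-alignment percent identity
(Needleman–Wunsch, match +1 / mismatch 0 / linear gap -1 by default) with a
fixed traceback tie-break (diagonal, then up, then left) so co-optimal
alignments resolve deterministically.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np

from .types import TmSegment, ValidationError

#: Kyte & Doolittle hydropathy scale; unknown residues score 0.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

DEFAULT_WINDOW = 19
DEFAULT_THRESHOLD = 1.6
DEFAULT_MIN_TM_LENGTH = 15
DEFAULT_MERGE_GAP = 3


def hydropathy_profile(sequence: str, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Sliding-window mean Kyte–Doolittle hydropathy at each window center.

    Returns one value per window position (length ``len(seq) - window + 1``).
    """
    scores = np.array([KYTE_DOOLITTLE.get(res, 0.0) for res in sequence.upper()])
    if len(scores) < window:
        return np.empty(0)
    kernel = np.ones(window) / window
    return np.convolve(scores, kernel, mode="valid")


def predict_tm_segments(
    sequence: str,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    min_tm_length: int = DEFAULT_MIN_TM_LENGTH,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> list[TmSegment]:
    """Call transmembrane segments from windowed hydropathy.

    A run of above-threshold window positions [i..j] (0-based window starts)
    is expanded to residues [i .. j + window - 1]; runs separated by at most
    ``merge_gap`` residues are merged; segments shorter than
    ``min_tm_length`` are discarded.  Coordinates are 1-based inclusive.
    """
    seq = sequence.upper()
    if len(seq) < window:
        warnings.warn(
            f"sequence length {len(seq)} < window {window}; no TM prediction",
            stacklevel=2,
        )
        return []
    profile = hydropathy_profile(seq, window)
    above = profile > threshold

    # maximal runs of above-threshold window starts
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    # expand to residue extent (0-based inclusive)
    spans = [(i, j + window - 1) for i, j in runs]

    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    scores = np.array([KYTE_DOOLITTLE.get(res, 0.0) for res in seq])
    segments = []
    for s, e in merged:
        if e - s + 1 >= min_tm_length:
            segments.append(
                TmSegment(
                    start=s + 1,
                    end=e + 1,
                    mean_hydropathy=float(scores[s : e + 1].mean()),
                )
            )
    return segments


def has_tm(
    sequences: Mapping[str, str] | None,
    accessions: Iterable[str],
    ingested_tm: Mapping[str, int] | None = None,
    **predict_kwargs,
) -> bool:
    """True iff any accession of a cluster has >= 1 TM segment.

    Evidence may come from hydropathy prediction on available sequences or
    from an ingested table of precomputed TM counts (accession -> n_tm);
    either source suffices.
    """
    for acc in accessions:
        if ingested_tm and ingested_tm.get(acc, 0) >= 1:
            return True
        if sequences and acc in sequences:
            seq = sequences[acc]
            if len(seq) >= predict_kwargs.get("window", DEFAULT_WINDOW) and predict_tm_segments(
                seq, **predict_kwargs
            ):
                return True
    return False


def _needleman_wunsch(
    a: str, b: str, match: float, mismatch: float, gap: float
) -> tuple[str, str]:
    """Global alignment with deterministic tie-break: diagonal > up > left."""
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = gap * np.arange(n + 1)
    score[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            up = score[i - 1, j] + gap
            left = score[i, j - 1] + gap
            score[i, j] = max(diag, up, left)
    # traceback
    ra, rb = [], []
    i, j = n, m
    while i > 0 or j > 0:
        cur = score[i, j]
        if i > 0 and j > 0 and cur == score[i - 1, j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            ra.append(a[i - 1]); rb.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and cur == score[i - 1, j] + gap:
            ra.append(a[i - 1]); rb.append("-"); i -= 1
        else:
            ra.append("-"); rb.append(b[j - 1]); j -= 1
    return "".join(reversed(ra)), "".join(reversed(rb))


def pairwise_percent_identity(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
) -> float:
    """Global-alignment percent identity between two sequences.

    identity = matching columns / alignment columns x 100, computed on the
    optimal Needleman–Wunsch alignment under (match, mismatch, linear gap)
    scoring with the fixed diagonal-first tie-break.
    """
    if not seq_a or not seq_b:
        raise ValidationError("cannot align an empty sequence")
    a, b = seq_a.upper(), seq_b.upper()
    aln_a, aln_b = _needleman_wunsch(a, b, match, mismatch, gap)
    matches = sum(x == y and x != "-" for x, y in zip(aln_a, aln_b))
    return 100.0 * matches / len(aln_a)


def segments_table(segments_by_acc: Mapping[str, Sequence[TmSegment]]):
    """Flatten predicted segments into rows (accession, start, end, gravy)."""
    import pandas as pd

    rows = [
        {
            "accession": acc,
            "start": seg.start,
            "end": seg.end,
            "gravy": seg.mean_hydropathy,
        }
        for acc in sorted(segments_by_acc)
        for seg in segments_by_acc[acc]
    ]
    return pd.DataFrame(rows, columns=["accession", "start", "end", "gravy"])
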