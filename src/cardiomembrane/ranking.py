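"""Equal-weight criterion scoring, rank ordering, the novel cardiac-enriched
subset, and per-compartment consort accounting.

Every cluster carries seven boolean criteria (membrane-fraction enrichment,
predicted TM segment, GO "membrane" term, cell-surface association, >= 3-fold
cardiac tissue enrichment, absence of a known cardiac phenotype, and
cross-species conservation); the score is their weighted sum with all
default weights equal, and ties rank alphabetically by gene symbol.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .types import (
    ALL_COMPARTMENTS,
    CRITERION_FLAGS,
    RankedCandidate,
    ValidationError,
)

DEFAULT_WEIGHTS: dict[str, float] = {flag: 1.0 for flag in CRITERION_FLAGS}


def score_candidate(
    flags: Mapping[str, bool], weights: Mapping[str, float] | None = None
) -> float:
    """Weighted sum of criterion flags (all weights 1 by default)."""
    weights = dict(weights) if weights is not None else DEFAULT_WEIGHTS
    unknown = set(weights) - set(CRITERION_FLAGS)
    if unknown:
        raise ValidationError(f"unknown criterion flags in weights: {sorted(unknown)}")
    if any(w < 0 for w in weights.values()):
        raise ValidationError("criterion weights must be >= 0")
    return float(sum(weights.get(f, 0.0) * bool(flags.get(f, False)) for f in CRITERION_FLAGS))


def rank_candidates(
    candidates: Iterable[RankedCandidate],
    weights: Mapping[str, float] | None = None,
) -> list[RankedCandidate]:
    """Score and order candidates: descending score, ties by gene symbol.

    Returns new objects with ``score`` and 1-based ``rank`` filled in;
    stable across reruns.
    """
    scored = []
    for c in candidates:
        scored.append(
            RankedCandidate(
                cluster=c.cluster,
                compartment=c.compartment,
                flags=dict(c.flags),
                score=score_candidate(c.flags, weights),
            )
        )
    scored.sort(key=lambda c: (-c.score, c.gene_symbol, c.cluster.human_accession))
    for i, c in enumerate(scored, start=1):
        c.rank = i
    return scored


def select_novel_cardiac(candidates: Iterable[RankedCandidate]) -> list[RankedCandidate]:
    """Candidates that are cardiac-enriched with no known cardiac phenotype."""
    return [c for c in candidates if c.is_novel_cardiac]


def top_candidates(
    ranked: Sequence[RankedCandidate], min_score: float | None = None, top_k: int | None = None
) -> list[RankedCandidate]:
    """Highest-ranked subset by score cutoff and/or top-k truncation."""
    out = list(ranked)
    if min_score is not None:
        out = [c for c in out if c.score >= min_score]
    if top_k is not None:
        out = out[:top_k]
    return out


def consort_counts(candidates: Iterable[RankedCandidate]) -> pd.DataFrame:
    """Per-compartment (total, cardiac-enriched, novel) tallies.

    ``novel`` counts clusters that are cardiac-enriched and carry no known
    cardiac phenotype; rows partition the input, so the total column sums
    to the number of candidates.
    """
    rows = {
        comp: {"n_total": 0, "n_cardiac_enriched": 0, "n_novel": 0}
        for comp in ALL_COMPARTMENTS
    }
    for c in candidates:
        comp = c.compartment
        if comp not in rows:
            raise ValidationError(f"unknown compartment {comp!r}")
        rows[comp]["n_total"] += 1
        if c.flags.get("cardiac_enriched"):
            rows[comp]["n_cardiac_enriched"] += 1
        if c.is_novel_cardiac:
            rows[comp]["n_novel"] += 1
    return pd.DataFrame.from_dict(rows, orient="index").loc[list(ALL_COMPARTMENTS)]


def ranked_frame(ranked: Sequence[RankedCandidate]) -> pd.DataFrame:
    """Flatten ranked candidates into the report table (deterministic columns)."""
    cols = [
        "rank",
        "gene_symbol",
        "human_accession",
        "mouse_accession",
        "compartment",
        *CRITERION_FLAGS,
        "score",
        "novel_cardiac",
    ]
    rows = []
    for c in ranked:
        row = {
            "rank": c.rank,
            "gene_symbol": c.gene_symbol,
            "human_accession": c.cluster.human_accession,
            "mouse_accession": c.cluster.mouse_accession,
            "compartment": c.compartment,
            "score": c.score,
            "novel_cardiac": c.is_novel_cardiac,
        }
        for f in CRITERION_FLAGS:
            row[f] = bool(c.flags.get(f, False))
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)
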