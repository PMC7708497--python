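"""GO cellular-component classification, membrane/cell-surface/phenotype flags,
and overlaps against external reference proteomes.

Each cluster receives exactly one compartment from a shipped keyword/ID
table, with a fixed precedence when annotations span several compartments
(mitochondrion > nucleus > plasma membrane > other organelle > secreted >
cytosol).  GO IDs are matched first; term-name keywords are the
case-insensitive fallback for sources that carry names only.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

from .types import (
    COMPARTMENTS,
    UNCLASSIFIED,
    AnnotationSet,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: GO CC IDs anchoring each compartment class.
COMPARTMENT_GO_IDS: dict[str, set[str]] = {
    "mitochondrion": {"GO:0005739", "GO:0005743", "GO:0005741", "GO:0005758"},
    "nucleus": {"GO:0005634", "GO:0005635", "GO:0005730", "GO:0031965"},
    "plasma_membrane": {"GO:0005886", "GO:0009986", "GO:0042383", "GO:0009897"},
    "other_organelle": {
        "GO:0005783",  # endoplasmic reticulum
        "GO:0005794",  # Golgi apparatus
        "GO:0005777",  # peroxisome
        "GO:0005764",  # lysosome
        "GO:0016529",  # sarcoplasmic reticulum
        "GO:0005768",  # endosome
    },
    "secreted": {"GO:0005576", "GO:0005615", "GO:0031012"},
    "cytosol": {"GO:0005829", "GO:0005856"},
}

#: Term-name keywords (case-insensitive substring match) per compartment.
COMPARTMENT_KEYWORDS: dict[str, tuple[str, ...]] = {
    "mitochondrion": ("mitochondri",),
    "nucleus": ("nucleus", "nuclear", "nucleolus", "nucleoplasm"),
    "plasma_membrane": ("plasma membrane", "cell surface", "sarcolemma"),
    "other_organelle": (
        "endoplasmic reticulum",
        "golgi",
        "peroxisom",
        "lysosom",
        "sarcoplasmic reticulum",
        "endosome",
        "vacuole",
    ),
    "secreted": ("extracellular", "secreted", "secretory"),
    "cytosol": ("cytosol", "cytoskeleton"),
}

MEMBRANE_GO_IDS = {"GO:0016020", "GO:0016021", "GO:0005886", "GO:0031966", "GO:0005887"}
CELL_SURFACE_GO_IDS = {"GO:0005886", "GO:0009986", "GO:0009897", "GO:0042383", "GO:0005887"}
CELL_SURFACE_KEYWORDS = (
    "plasma membrane",
    "cell surface",
    "sarcolemma",
    "external side",
)
CARDIAC_PHENOTYPE_KEYWORDS = ("cardiac", "heart", "cardiovascular", "myocard")


def _term_hits(terms: Iterable, go_ids: set[str], keywords: Iterable[str]) -> bool:
    for term in terms:
        go_id, name = term if isinstance(term, tuple) else ("", str(term))
        if go_id in go_ids:
            return True
        lname = (name or "").lower()
        if any(kw in lname for kw in keywords):
            return True
    return False


def classify_compartment(
    terms: Iterable,
    precedence: tuple[str, ...] = COMPARTMENTS,
) -> str:
    """Assign exactly one compartment class from a GO CC term set.

    ``terms`` is a set of (go_id, go_name) tuples (either element may be
    empty) or bare term-name strings.  Multi-compartment hits resolve by
    ``precedence``; no hit (or an empty set) yields ``"unclassified"``.
    """
    unknown = set(precedence) - set(COMPARTMENTS)
    if unknown:
        raise ValidationError(f"unknown compartments in precedence: {sorted(unknown)}")
    terms = list(terms)
    hits = [
        comp
        for comp in precedence
        if _term_hits(terms, COMPARTMENT_GO_IDS[comp], COMPARTMENT_KEYWORDS[comp])
    ]
    if len(hits) > 1:
        logger.debug("multi-compartment terms %s resolved to %s", terms, hits[0])
    return hits[0] if hits else UNCLASSIFIED


def membrane_and_surface_flags(terms: Iterable) -> tuple[bool, bool]:
    """(has GO "membrane" term, is cell-surface associated)."""
    terms = list(terms)
    has_membrane = False
    for term in terms:
        go_id, name = term if isinstance(term, tuple) else ("", str(term))
        if go_id in MEMBRANE_GO_IDS or "membrane" in (name or "").lower():
            has_membrane = True
            break
    is_surface = _term_hits(terms, CELL_SURFACE_GO_IDS, CELL_SURFACE_KEYWORDS)
    return has_membrane, is_surface


def cardiac_phenotype_flag(gene_symbol: str, annotations: AnnotationSet) -> bool:
    """True iff the gene carries any cardiac/heart phenotype annotation.

    Gene symbols compare case-insensitively; a gene absent from the flag
    table is treated as unflagged (logged).
    """
    key = gene_symbol.upper()
    if key not in annotations.mgi_cardiac_phenotype:
        logger.debug("gene %s absent from phenotype table; assuming no flag", gene_symbol)
        return False
    return bool(annotations.mgi_cardiac_phenotype[key])


def overlap_report(
    candidates: Iterable[str], references: Mapping[str, Iterable[str]]
) -> dict[str, dict[str, int]]:
    """Set overlaps between the candidate symbols and named reference lists.

    Symbols are upper-cased on both sides.  For each reference the report
    gives ``in_both``, ``only_candidates`` and ``only_reference``;
    ``in_both + only_candidates`` always equals the candidate-set size.
    """
    cand = {str(s).upper() for s in candidates}
    out = {}
    for name, ref in references.items():
        refset = {str(s).upper() for s in ref}
        both = cand & refset
        out[name] = {
            "in_both": len(both),
            "only_candidates": len(cand - refset),
            "only_reference": len(refset - cand),
        }
    return out
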