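"""Core in-memory containers shared by every pipeline stage.

The pipeline operates on one-to-one human/mouse orthologue clusters.  A
cluster carries spectral-count evidence from two subcellular fractions
(membrane-enriched vs membrane-depleted homogenate), a protein sequence per
species, Gene Ontology cellular-component annotations, a mouse phenotype
flag, and a row in a gene-by-tissue expression matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SPECIES = ("human", "mouse")

FRACTION_MEMBRANE = "membrane"
FRACTION_HOMOGENATE = "homogenate"
FRACTIONS = (FRACTION_MEMBRANE, FRACTION_HOMOGENATE)

#: Mutually exclusive subcellular compartment classes, in classifier
#: precedence order (earlier wins on multi-compartment annotation).
COMPARTMENTS = (
    "mitochondrion",
    "nucleus",
    "plasma_membrane",
    "other_organelle",
    "secreted",
    "cytosol",
)
UNCLASSIFIED = "unclassified"
ALL_COMPARTMENTS = COMPARTMENTS + (UNCLASSIFIED,)

#: Ranking criterion flags, each contributing its weight to the score.
CRITERION_FLAGS = (
    "membrane_enriched",
    "has_tm",
    "has_go_membrane",
    "is_cell_surface",
    "cardiac_enriched",
    "no_cardiac_phenotype",
    "conserved",
)


class FormatError(ValueError):
    """A file does not conform to its expected external format."""


class ValidationError(ValueError):
    """Well-formed input whose content violates a pipeline invariant."""


@dataclass
class ProteinRecord:
    """One identified protein in one species."""

    accession: str
    gene_symbol: str
    species: str
    sequence: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("accession must be non-empty")


@dataclass(frozen=True)
class OrthoCluster:
    """A one-to-one human/mouse protein pair analyzed as a single unit.

    ``accessions`` holds every accession whose evidence was folded into the
    cluster (grows under identifier amalgamation).
    """

    human_accession: str
    mouse_accession: str
    gene_symbol: str
    accessions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValidationError("gene_symbol must be non-empty")
        if not self.accessions:
            object.__setattr__(
                self, "accessions", (self.human_accession, self.mouse_accession)
            )

    @property
    def cluster_id(self) -> str:
        return f"{self.human_accession}|{self.mouse_accession}"


class SpectralCountTable:
    """Spectral counts per (protein, sample) with fraction/replicate labels.

    Parameters
    ----------
    counts
        Integer DataFrame, proteins (accessions) x samples.
    sample_meta
        DataFrame indexed by sample id with columns ``fraction`` (one of
        ``membrane``/``homogenate``), ``replicate`` (int) and optionally
        ``species``.
    """

    def __init__(self, counts: pd.DataFrame, sample_meta: pd.DataFrame):
        counts = counts.copy()
        meta = sample_meta.copy()
        if list(counts.columns) != list(meta.index):
            missing = set(counts.columns) ^ set(meta.index)
            raise ValidationError(
                f"counts columns and sample_meta index disagree: {sorted(missing)}"
            )
        vals = counts.to_numpy()
        if np.any(vals < 0):
            raise ValidationError("spectral counts must be >= 0")
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError("spectral counts must be integers")
        bad = set(meta["fraction"]) - set(FRACTIONS)
        if bad:
            raise ValidationError(f"unknown fraction labels: {sorted(bad)}")
        self.counts = counts.astype(np.int64)
        self.sample_meta = meta

    @property
    def proteins(self) -> pd.Index:
        return self.counts.index

    def samples_for(self, fraction: str) -> list:
        m = self.sample_meta["fraction"] == fraction
        return list(self.sample_meta.index[m])

    def pooled(self, fraction: str) -> pd.Series:
        """Counts summed over all samples of one fraction."""
        return self.counts[self.samples_for(fraction)].sum(axis=1)

    def library_sizes(self) -> pd.Series:
        """Total counts per sample."""
        return self.counts.sum(axis=0)

    def subset(self, proteins: Iterable[str]) -> "SpectralCountTable":
        idx = [p for p in proteins if p in self.counts.index]
        return SpectralCountTable(self.counts.loc[idx], self.sample_meta)


class ExpressionMatrix:
    """Nonnegative gene x tissue expression values with a designated heart set."""

    def __init__(
        self,
        values: pd.DataFrame,
        heart_tissues: Iterable[str] = ("heart",),
        units: str = "arbitrary",
    ):
        values = values.copy().astype(float)
        if (values.to_numpy() < 0).any():
            raise ValidationError("expression values must be nonnegative")
        heart = tuple(heart_tissues)
        missing = [t for t in heart if t not in values.columns]
        if not heart or missing:
            raise ValidationError(
                f"heart tissue set must be non-empty and present in columns; missing {missing}"
            )
        self.values = values
        self.heart_tissues = heart
        self.units = units

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def tissues(self) -> pd.Index:
        return self.values.columns

    @property
    def non_heart_tissues(self) -> list[str]:
        return [t for t in self.values.columns if t not in self.heart_tissues]


@dataclass
class AnnotationSet:
    """GO cellular-component terms, MGI cardiac-phenotype flags and reference lists.

    ``gocc_terms`` maps accession -> set of (go_id, go_name) pairs; either
    element may be an empty string when the source table carries only one of
    the two.  ``mgi_cardiac_phenotype`` maps upper-cased gene symbol -> bool.
    ``reference_lists`` maps a list name -> set of upper-cased gene symbols.
    """

    gocc_terms: dict = field(default_factory=dict)
    mgi_cardiac_phenotype: dict = field(default_factory=dict)
    reference_lists: dict = field(default_factory=dict)

    def terms_for(self, accessions: Iterable[str]) -> set:
        out: set = set()
        for acc in accessions:
            out |= self.gocc_terms.get(acc, set())
        return out


@dataclass
class Dataset:
    """Everything one pipeline run consumes, with cross-reference checking."""

    proteins: list = field(default_factory=list)
    counts: SpectralCountTable | None = None
    orthologs: list = field(default_factory=list)  # (human_acc, mouse_acc) pairs
    expression: ExpressionMatrix | None = None
    annotations: AnnotationSet = field(default_factory=AnnotationSet)
    provenance: str = ""

    def protein_index(self) -> dict:
        return {p.accession: p for p in self.proteins}

    def by_species(self, species: str) -> list:
        return [p for p in self.proteins if p.species == species]

    def orphans(self) -> dict:
        """Accessions referenced elsewhere that resolve to no ProteinRecord."""
        known = set(self.protein_index())
        out: dict[str, set] = {}
        if self.counts is not None:
            o = set(self.counts.proteins) - known
            if o:
                out["counts"] = o
        o = {a for pair in self.orthologs for a in pair} - known
        if o:
            out["orthologs"] = o
        o = set(self.annotations.gocc_terms) - known
        if o:
            out["annotations"] = o
        return out


@dataclass
class TmSegment:
    """A predicted transmembrane segment, 1-based inclusive coordinates."""

    start: int
    end: int
    mean_hydropathy: float

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(f"bad TM segment bounds {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class EnrichmentResult:
    """Membrane-vs-homogenate differential result for one protein/cluster."""

    protein: str
    log2_fold_change: float
    p_value: float
    fdr_q: float
    enriched: bool


@dataclass
class RankedCandidate:
    """An orthologue cluster with criterion flags, compartment, score and rank."""

    cluster: OrthoCluster
    compartment: str
    flags: Mapping[str, bool]
    score: float = 0.0
    rank: int = 0

    @property
    def gene_symbol(self) -> str:
        return self.cluster.gene_symbol

    @property
    def is_novel_cardiac(self) -> bool:
        return bool(
            self.flags.get("cardiac_enriched") and self.flags.get("no_cardiac_phenotype")
        )
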