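"""End-to-end orchestration: orthology -> enrichment -> flags -> ranking ->
consort/heatmap/overlap outputs, plus verification of a ranking workbook.

The analysis path is fully deterministic; randomness exists only in the
synthetic-data generator.  Every stage's before/after counts are recorded in
the machine-readable run summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__, io_formats
from .annotate import (
    cardiac_phenotype_flag,
    classify_compartment,
    membrane_and_surface_flags,
    overlap_report,
)
from .enrichment import results_frame, test_enrichment
from .orthology import amalgamate_ids, map_one_to_one
from .ranking import (
    consort_counts,
    rank_candidates,
    ranked_frame,
    select_novel_cardiac,
    top_candidates,
)
from .seqfeatures import has_tm
from .tissue import (
    DEFAULT_FOLD_THRESHOLD,
    cardiac_fold,
    heatmap_matrix,
    is_cardiac_enriched,
)
from .types import (
    ALL_COMPARTMENTS,
    COMPARTMENTS,
    Dataset,
    RankedCandidate,
    SpectralCountTable,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Thresholds and switches of the analysis path."""

    fold_threshold: float = DEFAULT_FOLD_THRESHOLD
    fold_inclusive: bool = True
    fold_aggregator: str = "median"
    fdr_q: float = 0.05
    enrichment_method: str = "auto"
    run_enrichment: bool = True
    tm_window: int = 19
    tm_threshold: float = 1.6
    tm_min_length: int = 15
    precedence: tuple = COMPARTMENTS
    weights: dict | None = None
    merge_map: dict = field(default_factory=dict)
    ingested_tm: dict = field(default_factory=dict)
    top_min_score: float | None = None
    top_k: int | None = None
    seed: int = 0


@dataclass
class PipelineResults:
    candidates: list
    ranked: pd.DataFrame
    consort: pd.DataFrame
    enrichment: pd.DataFrame
    heatmaps: dict
    overlaps: dict
    summary: dict

    @property
    def novel(self) -> pd.DataFrame:
        return self.ranked[self.ranked["novel_cardiac"]]


def _cluster_counts(dataset: Dataset, clusters) -> SpectralCountTable:
    """Sum member-accession spectral counts into one row per cluster."""
    counts = dataset.counts.counts
    rows = []
    for c in clusters:
        members = [a for a in c.accessions if a in counts.index]
        if members:
            rows.append(counts.loc[members].sum(axis=0).rename(c.gene_symbol))
        else:
            rows.append(
                pd.Series(0, index=counts.columns, name=c.gene_symbol, dtype=np.int64)
            )
    mat = pd.DataFrame(rows)
    mat.index.name = "cluster"
    return SpectralCountTable(mat, dataset.counts.sample_meta)


def analyze_dataset(dataset: Dataset, params: PipelineParams | None = None) -> PipelineResults:
    """Run the full candidate-prioritization analysis on an in-memory Dataset."""
    params = params or PipelineParams()
    summary: dict = {
        "version": __version__,
        "provenance": dataset.provenance,
        "seed": params.seed,
        "thresholds": {
            "fold_threshold": params.fold_threshold,
            "fold_inclusive": params.fold_inclusive,
            "fdr_q": params.fdr_q,
            "tm_window": params.tm_window,
            "tm_threshold": params.tm_threshold,
            "tm_min_length": params.tm_min_length,
        },
        "stages": {},
    }
    orphans = dataset.orphans()
    if orphans:
        logger.warning("orphan accessions: %s", {k: len(v) for k, v in orphans.items()})
    summary["orphans"] = {k: sorted(v) for k, v in orphans.items()}

    human = dataset.by_species("human")
    mouse = dataset.by_species("mouse")
    summary["stages"]["input"] = {
        "human_proteins": len(human),
        "mouse_proteins": len(mouse),
        "ortholog_pairs": len(dataset.orthologs),
    }

    clusters = map_one_to_one(human, mouse, dataset.orthologs)
    summary["stages"]["orthology"] = {
        "pairs_in": len(dataset.orthologs),
        "clusters_out": len(clusters),
    }

    if params.merge_map:
        before = len(clusters)
        clusters = amalgamate_ids(clusters, params.merge_map)
        summary["stages"]["amalgamation"] = {
            "clusters_in": before,
            "clusters_out": len(clusters),
        }

    # membrane-fraction enrichment (skippable when input is post-enrichment)
    enrichment_df = pd.DataFrame()
    membrane_flags: dict[str, bool] = {}
    if params.run_enrichment and dataset.counts is not None:
        cluster_table = _cluster_counts(dataset, clusters)
        results = test_enrichment(
            cluster_table,
            alpha_q=params.fdr_q,
            method=params.enrichment_method,
        )
        enrichment_df = results_frame(results)
        membrane_flags = {r.protein: r.enriched for r in results}
        summary["stages"]["membrane_enrichment"] = {
            "clusters_tested": len(results),
            "clusters_enriched": int(sum(r.enriched for r in results)),
        }
    else:
        membrane_flags = {c.gene_symbol: True for c in clusters}
        summary["stages"]["membrane_enrichment"] = {"skipped": True}

    sequences = {p.accession: p.sequence for p in dataset.proteins if p.sequence}
    expr = dataset.expression
    candidates = []
    n_missing_expression = 0
    for c in clusters:
        if not membrane_flags.get(c.gene_symbol, False):
            continue
        terms = dataset.annotations.terms_for(c.accessions)
        compartment = classify_compartment(terms, precedence=params.precedence)
        go_membrane, cell_surface = membrane_and_surface_flags(terms)
        pheno = cardiac_phenotype_flag(c.gene_symbol, dataset.annotations)
        tm = has_tm(
            sequences,
            c.accessions,
            ingested_tm=params.ingested_tm,
            window=params.tm_window,
            threshold=params.tm_threshold,
            min_tm_length=params.tm_min_length,
        )
        if expr is not None and c.gene_symbol in expr.values.index:
            fold = cardiac_fold(
                expr.values.loc[c.gene_symbol],
                expr.heart_tissues,
                aggregator=params.fold_aggregator,
            )
            cardiac = is_cardiac_enriched(
                fold, threshold=params.fold_threshold, inclusive=params.fold_inclusive
            )
        else:
            n_missing_expression += 1
            cardiac = False
        flags = {
            "membrane_enriched": bool(membrane_flags.get(c.gene_symbol, False)),
            "has_tm": tm,
            "has_go_membrane": go_membrane,
            "is_cell_surface": cell_surface,
            "cardiac_enriched": cardiac,
            "no_cardiac_phenotype": not pheno,
            "conserved": True,
        }
        candidates.append(RankedCandidate(cluster=c, compartment=compartment, flags=flags))

    if n_missing_expression:
        logger.warning("%d clusters missing from the expression matrix", n_missing_expression)
    summary["stages"]["flags"] = {
        "candidates": len(candidates),
        "missing_expression": n_missing_expression,
    }

    ranked = rank_candidates(candidates, weights=params.weights)
    novel = select_novel_cardiac(ranked)
    consort = consort_counts(ranked)
    top = top_candidates(ranked, min_score=params.top_min_score, top_k=params.top_k)
    summary["stages"]["ranking"] = {
        "ranked": len(ranked),
        "novel_cardiac": len(novel),
        "top_candidates": len(top),
    }
    summary["consort"] = {
        comp: {k: int(v) for k, v in row.items()} for comp, row in consort.iterrows()
    }

    heatmaps = {}
    if expr is not None and novel:
        for comp in ALL_COMPARTMENTS:
            genes = [c.gene_symbol for c in novel if c.compartment == comp]
            genes = [g for g in genes if g in expr.values.index]
            if genes:
                heatmaps[comp] = heatmap_matrix(expr, genes)

    overlaps = {}
    if dataset.annotations.reference_lists:
        overlaps = overlap_report(
            [c.gene_symbol for c in ranked], dataset.annotations.reference_lists
        )
        summary["overlaps"] = overlaps

    return PipelineResults(
        candidates=ranked,
        ranked=ranked_frame(ranked),
        consort=consort,
        enrichment=enrichment_df,
        heatmaps=heatmaps,
        overlaps=overlaps,
        summary=summary,
    )


# ---------------------------------------------------------------------------
# file-driven entry point


@dataclass
class PipelineConfig:
    """File paths plus analysis parameters for a configured run."""

    human_proteins: str
    mouse_proteins: str
    orthologs: str
    out_dir: str
    counts: str | None = None
    samples: str | None = None
    fasta: str | None = None
    go_annotations: str | None = None
    phenotypes: str | None = None
    expression: str | None = None
    heart_tissues: tuple = ("heart",)
    reference_lists: dict = field(default_factory=dict)
    merge_map: str | None = None
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        params = PipelineParams(**raw.pop("params", {}))
        if "heart_tissues" in raw:
            raw["heart_tissues"] = tuple(raw["heart_tissues"])
        return cls(params=params, **raw)

    def validate(self) -> None:
        required = {
            "human_proteins": self.human_proteins,
            "mouse_proteins": self.mouse_proteins,
            "orthologs": self.orthologs,
        }
        optional = {
            "counts": self.counts,
            "samples": self.samples,
            "fasta": self.fasta,
            "go_annotations": self.go_annotations,
            "phenotypes": self.phenotypes,
            "expression": self.expression,
            "merge_map": self.merge_map,
        }
        for name, p in {**required, **{k: v for k, v in optional.items() if v}}.items():
            if not Path(p).exists():
                raise ValidationError(f"config path for '{name}' does not exist: {p}")


def load_dataset(config: PipelineConfig) -> Dataset:
    """Assemble a Dataset from the files a PipelineConfig names."""
    from .io_formats import (
        read_counts,
        read_expression,
        read_fasta,
        read_go_annotations,
        read_ortholog_pairs,
        read_phenotype_flags,
        read_protein_table,
        read_reference_list,
    )
    from .types import AnnotationSet

    proteins = read_protein_table(config.human_proteins, "human") + read_protein_table(
        config.mouse_proteins, "mouse"
    )
    if config.fasta:
        seqs = read_fasta(config.fasta)
        for p in proteins:
            p.sequence = seqs.get(p.accession)
    counts = (
        read_counts(config.counts, config.samples)
        if config.counts and config.samples
        else None
    )
    annotations = AnnotationSet(
        gocc_terms=read_go_annotations(config.go_annotations)
        if config.go_annotations
        else {},
        mgi_cardiac_phenotype=read_phenotype_flags(config.phenotypes)
        if config.phenotypes
        else {},
        reference_lists={
            name: read_reference_list(p) for name, p in config.reference_lists.items()
        },
    )
    expression = (
        read_expression(config.expression, heart_tissues=config.heart_tissues)
        if config.expression
        else None
    )
    return Dataset(
        proteins=proteins,
        counts=counts,
        orthologs=read_ortholog_pairs(config.orthologs),
        expression=expression,
        annotations=annotations,
        provenance=str(config.human_proteins),
    )


def run_pipeline(config: PipelineConfig) -> PipelineResults:
    """Validate the config, run the analysis, write all report files."""
    config.validate()
    dataset = load_dataset(config)
    params = config.params
    if config.merge_map:
        from .orthology import read_merge_map

        params.merge_map = read_merge_map(config.merge_map)
    results = analyze_dataset(dataset, params)
    io_formats.write_report(results, config.out_dir)
    return results


# ---------------------------------------------------------------------------
# workbook verification

#: Quantities `verify_against_workbook` recomputes from workbook columns.
WORKBOOK_TARGETS = (
    "total_clusters",
    "novel_total",
    "compartment_counts",
    "cardiac_enriched_by_compartment",
    "novel_by_compartment",
    "top_candidate_count",
)

_TRUTHY = {"1", "true", "yes", "y", "t"}


def _as_bool(series: pd.Series) -> pd.Series:
    return series.map(
        lambda v: bool(v) if isinstance(v, (bool, np.bool_)) else
        (float(v) != 0 if isinstance(v, (int, float, np.integer, np.floating)) else
         str(v).strip().lower() in _TRUTHY)
    )


def verify_against_workbook(
    workbook_path: str | Path,
    alias_map: Mapping | None = None,
    expected: Mapping | None = None,
) -> dict:
    """Recompute headline counts from a ranking workbook's own columns.

    For each target quantity the report carries ``status`` (``evaluated`` or
    ``not_evaluable``), the recomputed ``value``, and — when ``expected``
    provides a reference — a ``match`` flag.  A missing file or unresolved
    required column yields ``not_evaluable`` statuses, never an exception.
    """
    report: dict = {t: {"status": "not_evaluable", "value": None} for t in WORKBOOK_TARGETS}
    path = Path(workbook_path)
    if not path.exists():
        report["error"] = f"workbook not found: {path}"
        return _apply_expected(report, expected)
    try:
        table = io_formats.read_ranking_workbook(path, alias_map=alias_map)
    except Exception as exc:  # noqa: BLE001
        report["error"] = f"unreadable workbook: {exc}"
        return _apply_expected(report, expected)

    report["total_clusters"] = {"status": "evaluated", "value": int(len(table))}

    comp_col = "compartment" if "compartment" in table.columns else "worksheet"
    comp_counts = table[comp_col].astype(str).value_counts().to_dict()
    report["compartment_counts"] = {
        "status": "evaluated",
        "value": {k: int(v) for k, v in sorted(comp_counts.items())},
    }

    if "cardiac_enriched" in table.columns:
        enriched = _as_bool(table["cardiac_enriched"])
        by_comp = (
            table.assign(_e=enriched).groupby(comp_col)["_e"].sum().astype(int).to_dict()
        )
        report["cardiac_enriched_by_compartment"] = {
            "status": "evaluated",
            "value": dict(sorted(by_comp.items())),
        }
        if "has_cardiac_phenotype" in table.columns:
            pheno = _as_bool(table["has_cardiac_phenotype"])
        elif "no_cardiac_phenotype" in table.columns:
            pheno = ~_as_bool(table["no_cardiac_phenotype"])
        else:
            pheno = None
        if pheno is not None:
            novel = enriched & ~pheno
            report["novel_total"] = {"status": "evaluated", "value": int(novel.sum())}
            nb = (
                table.assign(_n=novel).groupby(comp_col)["_n"].sum().astype(int).to_dict()
            )
            report["novel_by_compartment"] = {
                "status": "evaluated",
                "value": dict(sorted(nb.items())),
            }

    if "score" in table.columns:
        scores = pd.to_numeric(table["score"], errors="coerce")
        if scores.notna().any():
            report["top_candidate_count"] = {
                "status": "evaluated",
                "value": int((scores == scores.max()).sum()),
            }

    return _apply_expected(report, expected)


def _apply_expected(report: dict, expected: Mapping | None) -> dict:
    if not expected:
        return report
    for target, ref in expected.items():
        entry = report.get(target)
        if not isinstance(entry, dict):
            continue
        if entry.get("status") != "evaluated":
            entry["match"] = None
        else:
            entry["match"] = entry["value"] == ref
            entry["expected"] = ref
    return report
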