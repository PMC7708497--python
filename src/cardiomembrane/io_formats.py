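"""Readers and writers for every external representation the pipeline touches.

TSV (tab-separated, UTF-8, header row) is the canonical tabular interchange;
XLSX is supported read-only for the supplementary ranking workbook.  All
writers produce deterministic column order so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    AnnotationSet,
    ExpressionMatrix,
    FormatError,
    ProteinRecord,
    SpectralCountTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

REQUIRED_PROTEIN_COLUMNS = ("accession", "gene_symbol")

#: Default header-alias map used to normalize ranking-workbook columns.  The
#: canonical names are the keys; values are case-insensitive aliases seen in
#: the wild.  Users can extend or replace it with a YAML file of the same
#: shape (see :func:`load_alias_map`).
DEFAULT_ALIAS_MAP: dict[str, list[str]] = {
    "gene_symbol": ["gene_symbol", "gene name", "gene", "symbol", "gene symbol"],
    "human_accession": ["human_accession", "human accession", "human uniprot"],
    "mouse_accession": ["mouse_accession", "mouse accession", "mouse uniprot"],
    "compartment": ["compartment", "organelle", "subcellular localization"],
    "cardiac_enriched": [
        "cardiac_enriched",
        "cardiac enriched",
        "heart enriched",
        ">=3-fold cardiac",
        "biogps enriched",
    ],
    "has_cardiac_phenotype": [
        "has_cardiac_phenotype",
        "mgi cardiac phenotype",
        "cardiac phenotype",
        "known cardiac phenotype",
    ],
    "has_tm": ["has_tm", "tm domain", "predicted tm", "tmhmm", "transmembrane"],
    "has_go_membrane": ["has_go_membrane", "go membrane", "membrane go term"],
    "is_cell_surface": ["is_cell_surface", "cell surface", "cell-surface"],
    "score": ["score", "total score", "criteria met"],
    "rank": ["rank", "ranking", "final rank"],
}


def read_protein_table(path: str | Path, species: str) -> list[ProteinRecord]:
    """Read a per-species protein identification TSV into records.

    Requires ``accession`` and ``gene_symbol`` columns; any further columns
    are preserved in ``record.extra``.  Duplicate accessions are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in REQUIRED_PROTEIN_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    dup = df["accession"][df["accession"].duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate accessions {dup}")
    extras = [c for c in df.columns if c not in REQUIRED_PROTEIN_COLUMNS]
    records = [
        ProteinRecord(
            accession=row["accession"],
            gene_symbol=row["gene_symbol"],
            species=species,
            extra={c: row[c] for c in extras},
        )
        for _, row in df.iterrows()
    ]
    logger.info("read %d protein records (%s) from %s", len(records), species, path)
    return records


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into accession -> upper-cased sequence.

    The accession is the first whitespace-separated token of the header.
    Non-standard residues are preserved.  An empty file yields an empty
    mapping with a warning.
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        raise FormatError(f"{path}: sequence data before first FASTA header")
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="") for acc, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_counts(path: str | Path, meta_path: str | Path) -> SpectralCountTable:
    """Read a counts TSV (first column = accession) plus a sample-metadata TSV."""
    counts = pd.read_csv(path, sep="\t", index_col=0).rename_axis(None)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0).rename_axis(None)
    if "fraction" not in meta.columns:
        raise FormatError(f"{meta_path}: missing required column 'fraction'")
    return SpectralCountTable(counts, meta)


def write_counts(table: SpectralCountTable, path: str | Path, meta_path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="accession")
    table.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


def read_expression(
    path: str | Path, heart_tissues: Iterable[str] = ("heart",), units: str = "arbitrary"
) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0).rename_axis(None)
    return ExpressionMatrix(df, heart_tissues=heart_tissues, units=units)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_ortholog_pairs(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("human_accession", "mouse_accession"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    return list(zip(df["human_accession"], df["mouse_accession"]))


def write_ortholog_pairs(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(pairs, columns=["human_accession", "mouse_accession"]).to_csv(
        path, sep="\t", index=False
    )


def read_go_annotations(path: str | Path) -> dict[str, set]:
    """Read GO CC TSV (accession, go_id, go_name) into accession -> term set."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "accession" not in df.columns:
        raise FormatError(f"{path}: missing required column 'accession'")
    out: dict[str, set] = {}
    for _, row in df.iterrows():
        out.setdefault(row["accession"], set()).add(
            (row.get("go_id", ""), row.get("go_name", ""))
        )
    return out


def write_go_annotations(gocc: Mapping[str, set], path: str | Path) -> None:
    rows = [
        {"accession": acc, "go_id": gid, "go_name": name}
        for acc in sorted(gocc)
        for gid, name in sorted(gocc[acc])
    ]
    pd.DataFrame(rows, columns=["accession", "go_id", "go_name"]).to_csv(
        path, sep="\t", index=False
    )


def read_phenotype_flags(path: str | Path) -> dict[str, bool]:
    """Read MGI-style phenotype TSV (gene_symbol, cardiac_flag) into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("gene_symbol", "cardiac_flag"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    truthy = {"1", "true", "yes", "y"}
    return {
        row["gene_symbol"].upper(): row["cardiac_flag"].strip().lower() in truthy
        for _, row in df.iterrows()
    }


def write_phenotype_flags(flags: Mapping[str, bool], path: str | Path) -> None:
    rows = [{"gene_symbol": g, "cardiac_flag": int(v)} for g, v in sorted(flags.items())]
    pd.DataFrame(rows, columns=["gene_symbol", "cardiac_flag"]).to_csv(
        path, sep="\t", index=False
    )


def read_reference_list(path: str | Path) -> set[str]:
    """One gene symbol per line; symbols compared upper-cased."""
    return {
        line.strip().upper()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    }


def load_alias_map(path: str | Path | None = None) -> dict[str, list[str]]:
    """Load the workbook column alias map, merging a user YAML over defaults."""
    amap = {k: list(v) for k, v in DEFAULT_ALIAS_MAP.items()}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for canon, aliases in user.items():
            amap.setdefault(canon, [])
            amap[canon] = list(dict.fromkeys(amap[canon] + list(aliases)))
    return amap


def _normalize_columns(df: pd.DataFrame, alias_map: Mapping[str, list[str]]) -> pd.DataFrame:
    lookup = {
        alias.strip().lower(): canon
        for canon, aliases in alias_map.items()
        for alias in aliases
    }
    renames = {
        col: lookup[col.strip().lower()]
        for col in df.columns
        if col.strip().lower() in lookup
    }
    return df.rename(columns=renames)


def read_ranking_workbook(
    path: str | Path, alias_map: Mapping[str, list[str]] | None = None
) -> pd.DataFrame:
    """Read a per-compartment ranking workbook into one long table.

    Each worksheet is assumed to hold the rank-ordered analysis of one
    subcellular compartment; rows are concatenated with a ``worksheet``
    column recording the sheet of origin, and headers are normalized to the
    canonical names via the alias map.  Unreadable sheets are skipped with a
    warning; an entirely unreadable workbook is an error.
    """
    from openpyxl import load_workbook

    alias_map = alias_map or DEFAULT_ALIAS_MAP
    wb = load_workbook(str(path), read_only=True, data_only=True)
    frames = []
    for ws in wb.worksheets:
        try:
            rows = list(ws.values)
            if not rows or all(c is None for c in rows[0]):
                raise FormatError("empty sheet")
            header = [str(c) if c is not None else "" for c in rows[0]]
            df = pd.DataFrame(rows[1:], columns=header)
            df = df.dropna(how="all")
            df = _normalize_columns(df, alias_map)
            df.insert(0, "worksheet", ws.title)
            frames.append(df)
            logger.info("workbook sheet %r: %d rows", ws.title, len(df))
        except Exception as exc:  # noqa: BLE001 - sheet-level isolation
            logger.warning("skipping unreadable sheet %r: %s", ws.title, exc)
    wb.close()
    if not frames:
        raise FormatError(f"{path}: no readable worksheets")
    return pd.concat(frames, ignore_index=True)


def write_ranking_workbook(
    ranked: pd.DataFrame, path: str | Path, sheet_column: str = "compartment"
) -> None:
    """Write a ranked-candidate table as a per-compartment XLSX workbook.

    One worksheet per distinct ``sheet_column`` value, mirroring the layout
    of supplementary ranking workbooks (and providing synthetic fixtures for
    :func:`cardiomembrane.pipeline.verify_against_workbook`).
    """
    from openpyxl import Workbook

    wb = Workbook()
    wb.remove(wb.active)
    cols = [c for c in ranked.columns if c != sheet_column]
    for sheet, sub in ranked.groupby(sheet_column, sort=True):
        ws = wb.create_sheet(title=str(sheet)[:31])
        ws.append(cols)
        for _, row in sub.iterrows():
            ws.append([_xlsx_value(row[c]) for c in cols])
    wb.save(str(path))


def _xlsx_value(v):
    if isinstance(v, (np.bool_,)):
        return bool(v)
    if isinstance(v, np.integer):
        return int(v)
    if isinstance(v, np.floating):
        return float(v)
    return v


def write_report(results, out_dir: str | Path) -> dict[str, Path]:
    """Write ranked candidates, consort counts and heatmap matrices.

    ``results`` is a :class:`cardiomembrane.pipeline.PipelineResults`-like
    object with attributes ``ranked`` (DataFrame), ``consort`` (DataFrame),
    ``heatmaps`` (mapping name -> DataFrame) and ``summary`` (dict).
    Returns the mapping of artifact name -> written path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ranked = results.ranked
    paths["ranked"] = out / "ranked_candidates.tsv"
    ranked.to_csv(paths["ranked"], sep="\t", index=False)

    paths["consort"] = out / "consort_counts.json"
    consort_payload = {
        "per_compartment": results.consort.to_dict(orient="index"),
        "totals": {
            col: int(results.consort[col].sum()) for col in results.consort.columns
        },
    }
    paths["consort"].write_text(json.dumps(consort_payload, indent=2, sort_keys=True) + "\n")

    for name, mat in getattr(results, "heatmaps", {}).items():
        p = out / f"heatmap_{name}.tsv"
        mat.to_csv(p, sep="\t", index_label="gene")
        paths[f"heatmap_{name}"] = p

    paths["summary"] = out / "run_summary.json"
    paths["summary"].write_text(
        json.dumps(results.summary, indent=2, sort_keys=True, default=str) + "\n"
    )
    return paths
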