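"""Synthetic dual-species membrane-proteomics datasets with planted truth.

The generator emulates the statistical structure the analysis assumes: a
set of human/mouse one-to-one orthologue clusters whose spectral counts are
negative-binomially distributed (overdispersion is the norm for spectral
counting), with a multiplicative membrane-fraction effect for planted
membrane proteins; protein sequences with unambiguous hydrophobic TM
stretches; log-normal tissue expression rows with a planted heart fold;
GO cellular-component terms consistent with a planted compartment label;
sparse cardiac phenotype flags; and a handful of non-one-to-one decoy
ortholog pairs that the orthology stage must exclude.

All randomness flows from one seed through named child streams, so a given
(config, seed) is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .annotate import COMPARTMENT_GO_IDS
from .types import (
    ALL_COMPARTMENTS,
    COMPARTMENTS,
    UNCLASSIFIED,
    AnnotationSet,
    Dataset,
    ProteinRecord,
    SpectralCountTable,
    ExpressionMatrix,
    ValidationError,
)

#: Compartment label frequencies used when planting subcellular classes,
#: matching the composition of a membrane-enriched cardiomyocyte proteome
#: (mitochondria-dominated, then nuclear envelope, plasma membrane, other
#: organelles, secreted, cytosolic, a small unclassifiable remainder).
COMPARTMENT_PROBS: dict[str, float] = {
    "mitochondrion": 0.41,
    "nucleus": 0.23,
    "plasma_membrane": 0.12,
    "other_organelle": 0.12,
    "secreted": 0.04,
    "cytosol": 0.06,
    UNCLASSIFIED: 0.02,
}

_CANONICAL_TERM: dict[str, tuple[str, str]] = {
    "mitochondrion": ("GO:0005739", "mitochondrion"),
    "nucleus": ("GO:0005634", "nucleus"),
    "plasma_membrane": ("GO:0005886", "plasma membrane"),
    "other_organelle": ("GO:0005783", "endoplasmic reticulum"),
    "secreted": ("GO:0005576", "extracellular region"),
    "cytosol": ("GO:0005829", "cytosol"),
}

HYDROPHOBIC = "LIVFA"
POLAR = "STNQDEKRGP"

TISSUES = (
    "heart",
    "brain",
    "liver",
    "kidney",
    "lung",
    "skeletal_muscle",
    "spleen",
    "stomach",
    "intestine",
    "pancreas",
    "thymus",
    "testis",
)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic dataset; defaults are the study conditions.

    ``enrichment_fold`` multiplies membrane-fraction count means for planted
    membrane proteins; ``cardiac_fold`` multiplies the heart column for
    planted cardiac-enriched genes; ``dispersion`` is the negative-binomial
    overdispersion (var = mu + dispersion * mu^2); ``tissue_log_sigma`` is
    the natural-log SD of tissue-to-tissue biological variation;
    ``disease_effect`` shifts disease-group means, in units of the
    within-group SD.
    """

    n_proteins: int = 500
    frac_membrane_true: float = 0.2
    enrichment_fold: float = 8.0
    baseline_count_mean: float = 10.0
    dispersion: float = 0.5
    n_replicates: int = 3
    frac_tm_true: float = 0.5
    n_tissues: int = len(TISSUES)
    frac_cardiac_enriched: float = 0.35
    cardiac_fold: float = 5.0
    frac_mgi_flagged: float = 0.2
    disease_effect: float = 2.0
    tissue_log_sigma: float = 0.3
    n_decoy_pairs: int = 5
    frac_go_membrane: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_membrane_true",
            "frac_tm_true",
            "frac_cardiac_enriched",
            "frac_mgi_flagged",
            "frac_go_membrane",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.enrichment_fold <= 0 or self.cardiac_fold <= 0:
            raise ValidationError("fold effects must be > 0")
        if self.n_proteins < 0 or self.n_replicates < 1:
            raise ValidationError("counts must be nonnegative / replicates >= 1")
        if not 2 <= self.n_tissues <= len(TISSUES):
            raise ValidationError(f"n_tissues must be in [2, {len(TISSUES)}]")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("labels", "sequences", "counts", "expression", "flags", "disease")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _make_sequence(
    rng: np.random.Generator, length: int, tm_positions: list[tuple[int, int]]
) -> str:
    residues = list(rng.choice(list(POLAR), size=length))
    for start, tm_len in tm_positions:
        for k in range(tm_len):
            residues[start + k] = str(rng.choice(list(HYDROPHOBIC)))
    return "".join(residues)


def generate_dataset(config: GeneratorConfig) -> tuple[Dataset, pd.DataFrame]:
    """Generate a full Dataset plus the planted-truth table.

    The truth table is indexed by gene symbol with one row per generated
    cluster and boolean columns ``is_membrane_enriched``, ``has_tm``,
    ``is_cardiac_enriched``, ``has_cardiac_phenotype`` and the string
    ``compartment_label``.
    """
    rngs = _streams(config.seed)
    n = config.n_proteins
    if n == 0:
        empty_counts = SpectralCountTable(
            pd.DataFrame(columns=["m1", "h1"], dtype=int),
            pd.DataFrame(
                {"fraction": ["membrane", "homogenate"], "replicate": [1, 1]},
                index=["m1", "h1"],
            ),
        )
        return (
            Dataset(counts=empty_counts, provenance="synthetic(empty)"),
            pd.DataFrame(
                columns=[
                    "human_accession",
                    "mouse_accession",
                    "is_membrane_enriched",
                    "has_tm",
                    "is_cardiac_enriched",
                    "has_cardiac_phenotype",
                    "compartment_label",
                ]
            ),
        )

    genes = [f"GENE{i:04d}" for i in range(n)]
    h_accs = [f"H{i:05d}" for i in range(n)]
    m_accs = [f"M{i:05d}" for i in range(n)]

    r = rngs["labels"]
    comp_names = list(COMPARTMENT_PROBS)
    comps = r.choice(comp_names, size=n, p=list(COMPARTMENT_PROBS.values()))
    is_mem = r.random(n) < config.frac_membrane_true
    has_tm = r.random(n) < config.frac_tm_true
    is_cardiac = r.random(n) < config.frac_cardiac_enriched
    has_pheno = r.random(n) < config.frac_mgi_flagged
    has_go_membrane = r.random(n) < config.frac_go_membrane

    # sequences (mouse = human with light loop mutations, TM preserved)
    rs = rngs["sequences"]
    sequences: dict[str, str] = {}
    for i in range(n):
        length = int(rs.integers(100, 401))
        tm_positions: list[tuple[int, int]] = []
        if has_tm[i]:
            n_tm = int(rs.integers(1, 4))
            cursor = int(rs.integers(5, 30))
            for _ in range(n_tm):
                tm_len = int(rs.integers(19, 24))
                if cursor + tm_len + 30 >= length:
                    break
                tm_positions.append((cursor, tm_len))
                cursor += tm_len + int(rs.integers(30, 60))
            if not tm_positions:  # short sequence: force one helix
                tm_len = int(rs.integers(19, 24))
                tm_positions.append((5, tm_len))
        human_seq = _make_sequence(rs, length, tm_positions)
        tm_mask = np.zeros(length, dtype=bool)
        for start, tm_len in tm_positions:
            tm_mask[start : start + tm_len] = True
        mouse = list(human_seq)
        mutate = (rs.random(length) < 0.05) & ~tm_mask
        for pos in np.nonzero(mutate)[0]:
            mouse[pos] = str(rs.choice(list(POLAR)))
        sequences[h_accs[i]] = human_seq
        sequences[m_accs[i]] = "".join(mouse)

    # spectral counts: per species x fraction x replicate
    rc = rngs["counts"]
    sample_ids, meta_rows = [], []
    for species in ("human", "mouse"):
        for fraction in ("membrane", "homogenate"):
            for rep in range(1, config.n_replicates + 1):
                sample_ids.append(f"{species}_{fraction}_r{rep}")
                meta_rows.append(
                    {"fraction": fraction, "replicate": rep, "species": species}
                )
    meta = pd.DataFrame(meta_rows, index=sample_ids)
    accs = h_accs + m_accs
    counts = np.zeros((2 * n, len(sample_ids)), dtype=np.int64)
    base = np.full(n, config.baseline_count_mean)
    for j, sid in enumerate(sample_ids):
        fraction = meta.loc[sid, "fraction"]
        species = meta.loc[sid, "species"]
        mean = base * np.where(
            is_mem & (fraction == "membrane"), config.enrichment_fold, 1.0
        )
        col = _nb_draw(rc, mean, config.dispersion)
        if species == "human":
            counts[:n, j] = col
        else:
            counts[n:, j] = col
    count_table = SpectralCountTable(
        pd.DataFrame(counts, index=accs, columns=sample_ids), meta
    )

    # tissue expression
    re_ = rngs["expression"]
    tissues = list(TISSUES[: config.n_tissues])
    gene_scale = np.exp(re_.normal(np.log(50.0), 1.0, size=n))
    noise = np.exp(re_.normal(0.0, config.tissue_log_sigma, size=(n, len(tissues))))
    expr = gene_scale[:, None] * noise
    heart_idx = tissues.index("heart")
    expr[is_cardiac, heart_idx] *= config.cardiac_fold
    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=genes, columns=tissues),
        heart_tissues=("heart",),
        units="synthetic_signal",
    )

    # annotations
    gocc: dict[str, set] = {}
    for i in range(n):
        terms: set = set()
        comp = comps[i]
        if comp != UNCLASSIFIED:
            terms.add(_CANONICAL_TERM[comp])
        if has_go_membrane[i]:
            terms.add(("GO:0016020", "membrane"))
        if terms:
            gocc[h_accs[i]] = set(terms)
            gocc[m_accs[i]] = set(terms)
    mgi = {genes[i]: bool(has_pheno[i]) for i in range(n)}
    annotations = AnnotationSet(gocc_terms=gocc, mgi_cardiac_phenotype=mgi)

    # proteins and ortholog pairs (+ non-one-to-one decoys)
    proteins = [
        ProteinRecord(h_accs[i], genes[i], "human", sequence=sequences[h_accs[i]])
        for i in range(n)
    ] + [
        ProteinRecord(m_accs[i], genes[i].lower().capitalize(), "mouse", sequence=sequences[m_accs[i]])
        for i in range(n)
    ]
    pairs = list(zip(h_accs, m_accs))
    for d in range(config.n_decoy_pairs):
        hd, md1, md2 = f"XH{d:03d}", f"XM{d:03d}A", f"XM{d:03d}B"
        gene = f"DECOY{d:03d}"
        proteins.append(ProteinRecord(hd, gene, "human", sequence=None))
        proteins.append(ProteinRecord(md1, gene, "mouse", sequence=None))
        proteins.append(ProteinRecord(md2, gene, "mouse", sequence=None))
        pairs.append((hd, md1))
        pairs.append((hd, md2))  # one-to-many: must be excluded downstream

    dataset = Dataset(
        proteins=proteins,
        counts=count_table,
        orthologs=pairs,
        expression=expression,
        annotations=annotations,
        provenance=f"synthetic(seed={config.seed})",
    )
    truth = pd.DataFrame(
        {
            "human_accession": h_accs,
            "mouse_accession": m_accs,
            "is_membrane_enriched": is_mem,
            "has_tm": has_tm,
            "is_cardiac_enriched": is_cardiac,
            "has_cardiac_phenotype": has_pheno,
            "compartment_label": comps,
        },
        index=pd.Index(genes, name="gene_symbol"),
    )
    return dataset, truth


def generate_disease_groups(
    config: GeneratorConfig,
    group_sizes: dict[str, int] | None = None,
    control_label: str = "control",
    mu: float = 100.0,
    sigma: float = 10.0,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Normalized-hybridization-signal groups: control plus shifted diseases.

    Control values are Normal(mu, sigma); each non-control group's mean is
    shifted by ``config.disease_effect`` in sigma units.  Group sizes below
    2 are rejected; a request for only the control group is honoured.
    """
    group_sizes = group_sizes or {control_label: 4, "DCM": 4, "ICM": 4}
    if control_label not in group_sizes:
        raise ValidationError(f"control group {control_label!r} missing from sizes")
    for name, size in group_sizes.items():
        if size < 2:
            raise ValidationError(f"group {name!r} size {size} < 2")
    rng = rng or _streams(config.seed)["disease"]
    out = {}
    for name, size in group_sizes.items():
        shift = 0.0 if name == control_label else config.disease_effect * sigma
        out[name] = rng.normal(mu + shift, sigma, size=size)
    return out


def write_dataset(
    dataset: Dataset, truth: pd.DataFrame, out_dir: str | Path
) -> dict[str, Path]:
    """Write a generated Dataset as the standard TSV/FASTA files plus truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for species in ("human", "mouse"):
        rows = [
            {"accession": p.accession, "gene_symbol": p.gene_symbol}
            for p in dataset.by_species(species)
        ]
        p = out / f"proteins_{species}.tsv"
        pd.DataFrame(rows, columns=["accession", "gene_symbol"]).to_csv(
            p, sep="\t", index=False
        )
        paths[f"proteins_{species}"] = p

    seqs = {p.accession: p.sequence for p in dataset.proteins if p.sequence}
    paths["fasta"] = out / "sequences.fasta"
    io_formats.write_fasta(seqs, paths["fasta"])

    if dataset.counts is not None:
        paths["counts"] = out / "counts.tsv"
        paths["samples"] = out / "samples.tsv"
        io_formats.write_counts(dataset.counts, paths["counts"], paths["samples"])

    paths["orthologs"] = out / "orthologs.tsv"
    io_formats.write_ortholog_pairs(dataset.orthologs, paths["orthologs"])

    paths["go"] = out / "go_annotations.tsv"
    io_formats.write_go_annotations(dataset.annotations.gocc_terms, paths["go"])

    paths["phenotypes"] = out / "phenotypes.tsv"
    io_formats.write_phenotype_flags(
        dataset.annotations.mgi_cardiac_phenotype, paths["phenotypes"]
    )

    if dataset.expression is not None:
        paths["expression"] = out / "expression.tsv"
        io_formats.write_expression(dataset.expression, paths["expression"])

    paths["truth"] = out / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t")
    return paths


def load_config(path: str | Path) -> GeneratorConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    return GeneratorConfig(**raw)


def config_dict(config: GeneratorConfig) -> dict:
    return asdict(config)
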