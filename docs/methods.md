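# Methods

This note records the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Orthology reduction

Candidates are human–mouse one-to-one orthologue clusters. Given a pair
table (human accession, mouse accession), a pair is retained only if both
endpoints have degree 1 in the bipartite graph restricted to the input
protein lists; one-to-many and many-to-one relations are excluded entirely.
The restriction to the input lists is deliberate: the analysis maps the
*identified* proteomes, so a genome-wide paralog that was never identified
should not disqualify a cluster. The alternative (degree computed on the
full pair table) is available via `restrict_to_inputs=False`.

Identifier amalgamation folds superseded accessions into their current
clusters by union–find, uniting count and annotation evidence; output size
equals input size minus effective merges, and merge cycles are an error.
A default merge map with five known duplicate-identifier pairs ships with
the package.

## Membrane-fraction enrichment

The reference analysis for this step in the field is QSpec, a Bayesian
hierarchical model over spectral counts. This package deliberately uses a
deterministic, oracle-checkable substitute:

* **Statistic.** Counts are pooled within each fraction. Conditional on the
  pooled total *n = M + H* of a protein, under the null of equal relative
  abundance *M* ~ Binomial(*n*, *π₀*).
* **Offset.** *π₀* is the null membrane share. With explicit library sizes
  it is the membrane share of the totals. By default it is the **median of
  the per-protein membrane proportions** (pseudocounted). Membrane-capture
  experiments shift a large mass fraction of the proteome into the membrane
  library, so a total-count offset would absorb genuine enrichment into the
  normalization and push unchanged proteins into apparent depletion; the
  median-of-proportions offset anchors the null on the typical protein, the
  same compositional argument behind median-of-ratios normalization in
  count-based differential expression. Tables with fewer than 8 nonzero
  proteins fall back to the total-count offset (a median over a handful of
  proteins is not an estimate of "typical").
* **Overdispersion.** Spectral counts are overdispersed relative to
  Poisson/binomial sampling. The default (`method="auto"` with ≥ 2
  replicate degrees of freedom) divides the score statistic
  *z² = (M − nπ₀)² / (nπ₀(1−π₀))* by a moderated Pearson dispersion φ̂:
  per-protein replicate residuals against library-share expectations give
  X²/df, shrunk toward the experiment-wide mean with 20 prior degrees of
  freedom (per-protein replicate df are tiny) and floored at 1; *z²/φ̂* is
  referred to χ²₁. With a single sample per fraction the exact two-sided
  binomial p-value (minimum-likelihood convention) is used instead, and
  `method="binomial"` forces it.
* **Fold change.** log₂FC = log₂[(M+½)/(H+½)] − log₂[π₀/(1−π₀)], i.e. the
  NSAF-scale ratio (protein length cancels within a protein). The ½
  pseudocount applies to the fold change only, never to the test's null.
* **Calls.** Benjamini–Hochberg across proteins; enriched ⇔ *q* ≤ 0.05 and
  log₂FC > 0. The identification-level "< 1% FDR" often quoted for
  peptide/protein identification is a different filter belonging to the
  upstream search, not to this step.

NSAF itself — (c/L) / Σ(c/L), summing to 1 per sample — is provided for
reporting; samples with zero total counts are excluded and flagged.

## Transmembrane segments and conservation

TM calling is the classic Kyte–Doolittle sliding-window heuristic: window
19, GRAVY threshold 1.6, minimum segment length 15, runs of above-threshold
window positions expanded to window extent and merged across gaps ≤ 3
residues. These are the textbook single-TM defaults; all four are
configurable. The heuristic is a transparent stand-in for HMM topology
predictors — it does not model orientation, signal peptides or marginal
helices — and externally computed TM calls can be ingested instead
(accession → TM count), taking the same downstream path. Coordinates are
1-based inclusive everywhere.

Percent identity uses global Needleman–Wunsch alignment with match +1,
mismatch 0, linear gap −1, identity = matches / alignment columns × 100.
Because co-optimal alignments can differ in identity, the traceback
tie-break is fixed (diagonal, then up, then left) so results are
deterministic; the scoring scheme is configurable since published
"homology" percentages rarely state theirs.

## Compartment classification and flags

Each cluster gets exactly one compartment from its GO cellular-component
terms via a shipped GO-ID table with case-insensitive name-keyword
fallback (supplementary tables often carry names only). Multi-compartment
annotation resolves by fixed precedence — mitochondrion > nucleus > plasma
membrane > other organelle > secreted > cytosol — chosen to produce the
mutually exclusive partition a consort diagram needs; the precedence is
config-exposed and multi-hits are logged. Empty or unmapped term sets are
"unclassified". The GO "membrane" flag and the cell-surface flag are
term-list lookups; the shipped cell-surface list is a best-effort default.
Phenotype flags are per-gene booleans (gene symbols compared upper-cased);
a gene absent from the flag table counts as unflagged, logged.

## Cardiac tissue enrichment

fold = max over heart columns / median of non-heart columns. The median is
robust to one outlier tissue (skeletal muscle commonly co-expresses
"cardiac" genes); mean and max are selectable. Multiple heart columns
(adult + fetal) are combined by max — a gene dominant in either is of
interest. Edge conventions: positive/0 → +∞, 0/0 → 0, all-missing → NaN
(never enriched). The threshold is 3.0 and **inclusive** by default
(published wordings mix "at least 3-fold" and "> 3-fold"; the flag is
logged and configurable). Heatmap rows are divided by their row totals
(all-zero rows stay zero and are flagged; the operation is idempotent) and
ordered by average-linkage agglomerative clustering on euclidean distances
(scipy linkage; deterministic for a given input).

## Ranking

score = Σ wᵢ·flagᵢ over the seven criteria (membrane enrichment, TM, GO
membrane, cell surface, cardiac enrichment, phenotype novelty,
conservation), default weights all 1 — each criterion counts equally. Ties
break alphabetically by gene symbol: reproducible and species-neutral. The
"novel cardiac-enriched" subset is cardiac_enriched ∧ no_cardiac_phenotype.
How a published analysis collapses scores into a "top candidates" set
(score cutoff vs top-k) is usually not stated, so both are exposed
(`top_min_score`, `top_k`); workbook verification counts rows achieving the
maximum score.

## Disease expression

One-way ANOVA in its classical decomposition, with the degenerate
zero-variance case reported as NaN/p = 1 rather than an error. Post hoc
pairwise comparisons use the studentized-range (Tukey HSD) distribution via
scipy's implementation, which applies the Tukey–Kramer allowance for
unequal group sizes; stars follow the usual convention (* p < 0.05,
** p < 0.01). The test suite cross-checks the adjusted p-values against a
100,000-permutation max-studentized-range oracle on a 3-group toy; the
permutation null and the normal-theory null are distinct references, so
agreement is asserted to 0.02 absolute, well above the Monte-Carlo error
but tight enough to catch a wrong distribution or a missing multiplicity
adjustment. Densitometric quantifications can be fed through the same path
as grouped signal tables.

## Synthetic data: what it emulates, and what it does not

The generator plants, per orthologue cluster: a membrane-enrichment label
(probability 0.2 — roughly the fraction of identified proteins that
survive enrichment testing in comparable experiments), a TM label (0.5), a
cardiac-enrichment label (0.35), a phenotype flag (0.2 — matching the
"only ~20% previously linked to cardiac phenotypes" regime), and a
compartment label drawn from a mitochondria-dominated distribution
(0.41/0.23/0.12/0.12/0.04/0.06/0.02 over the seven classes).

* **Counts** are negative-binomial, mean 10 per replicate, dispersion 0.5
  (var = μ + 0.5μ²; strong overdispersion is the norm for spectral
  counts), 3 replicates per fraction per species, with the membrane-fraction
  mean multiplied by the enrichment fold (default 8) for planted proteins.
* **Sequences** are 100–400 residues; loops draw from polar residues
  {S,T,N,Q,D,E,K,R,G,P}, planted TM helices (19–23 residues) from
  {L,I,V,F,A} — an intentionally unambiguous hydropathy contrast, so TM
  recovery tests the caller, not the generator. Mouse sequences are the
  human sequence with 5% loop mutations, leaving TM placement intact.
* **Expression** rows are log-normal: per-gene scale × per-tissue noise
  with natural-log SD 0.3 (moderate tissue-to-tissue biological
  variability; at this SD a planted 5-fold heart effect clears the 3-fold
  threshold in ~93% of genes, and spurious 3-fold calls are rare), heart
  column multiplied by the cardiac fold (default 5) for planted genes.
* **Decoys**: a configurable number of extra protein triples wired as
  one-to-many ortholog pairs, which the orthology stage must exclude.
* **Disease groups**: control ~ Normal(100, 10), disease groups shifted by
  `disease_effect` standard deviations, 3–5 values per group.

All streams derive from one seed through named `SeedSequence` children, so
identical (config, seed) reproduces the dataset exactly.

What it does **not** emulate: peptide-level identification and FDR
filtering, shared/razor peptides, protein length–count coupling beyond
NSAF's own correction, correlated tissues, batch effects, probe-level
microarray structure, or annotation errors. Passing the planted-truth tests
therefore demonstrates that the pipeline's inference is correct under its
own statistical assumptions, not that those assumptions capture every
pathology of real MS data.

## Problem sizes and numerical conventions

The planted-truth acceptance run uses 500 clusters, enrichment fold 8,
cardiac fold 5; calibration uses 1,000 null ANOVA simulations and 300 × 50
null enrichment tables (15,000 p-values); the Tukey cross-check uses
100,000 permutations in tests and 20,000 in the acceptance script. These
sizes give stable rates while keeping a full run in the seconds-to-minutes
range on a single CPU. Ranking and all analysis paths are deterministic;
only the generator consumes randomness. Sample permutation invariance,
NSAF per-sample unit sums, compartment partition conservation and consort
total conservation are asserted as properties in the suite.

## Known limitations

* The enrichment substitute shares QSpec's goal but not its hierarchical
  shrinkage; very low-count proteins lean on the moderated dispersion and
  the pseudocounted fold change.
* The compartment classifier does no GO-graph traversal; terms are matched
  directly, so annotations phrased only via obscure descendant terms fall
  to the keyword fallback or to "unclassified".
* The TM heuristic under-calls marginal or strongly amphipathic helices by
  construction.
* Reference overlap lists (e.g. external membrane-proteome or heart-proteome
  gene sets) are user-supplied files; nothing is fetched at runtime.
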