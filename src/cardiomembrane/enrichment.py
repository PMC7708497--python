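"""Membrane-fraction differential enrichment from spectral counts.

The published analysis used QSpec, a Bayesian hierarchical model for
spectral-count data.  This module provides a deterministic, oracle-checkable
substitute built on the pooled-count conditional test:

* For each protein, counts are pooled within each fraction (membrane vs
  membrane-depleted homogenate).  Conditional on the pooled total
  ``n = n_mem + n_hom``, under the null of equal relative abundance the
  membrane count is Binomial(n, pi0) with ``pi0`` the membrane share of the
  library sizes — the standard two-proportion test with library-size offset.
* ``method="binomial"`` computes the exact two-sided binomial p-value
  (minlike: sum of outcome probabilities no larger than the observed one).
* ``method="quasibinomial"`` (the default when replicate degrees of freedom
  allow) inflates the score-test variance by a moderated Pearson dispersion
  estimated from between-replicate variation, which keeps the test calibrated
  under the overdispersion typical of spectral counts.

Fold changes are reported on the NSAF (length-normalized, per-sample
sum-to-one) scale; for the membrane/homogenate ratio of one protein the
length term cancels, so the ratio reduces to library-size-normalized pooled
counts with a 0.5 pseudocount (applied to the fold change only, never to the
test's null).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import (
    FRACTION_HOMOGENATE,
    FRACTION_MEMBRANE,
    EnrichmentResult,
    SpectralCountTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 0.5
#: Prior degrees of freedom pulling per-protein dispersion toward the
#: experiment-wide value (replicate df per protein are tiny).
DISPERSION_PRIOR_DF = 20.0


def nsaf_normalize(
    table: SpectralCountTable, lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Normalized Spectral Abundance Factor per (protein, sample).

    NSAF(p, s) = (c_ps / L_p) / sum_q (c_qs / L_q); each sample column sums
    to 1.  Samples with zero total counts are excluded (dropped from the
    returned frame) and logged.
    """
    missing = [p for p in table.proteins if p not in lengths]
    if missing:
        raise ValidationError(f"missing sequence lengths for {missing[:5]}...")
    lens = np.array([lengths[p] for p in table.proteins], dtype=float)
    if np.any(lens <= 0):
        raise ValidationError("protein lengths must be > 0")
    saf = table.counts.to_numpy(dtype=float) / lens[:, None]
    totals = saf.sum(axis=0)
    dead = totals == 0
    if dead.any():
        excluded = list(table.counts.columns[dead])
        logger.warning("samples with zero total counts excluded from NSAF: %s", excluded)
    nsaf = saf[:, ~dead] / totals[~dead]
    return pd.DataFrame(
        nsaf, index=table.proteins, columns=table.counts.columns[~dead]
    )


def _binom_p_two_sided(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p-value (minlike convention)."""
    if n == 0:
        return 1.0
    return stats.binomtest(int(k), int(n), p0, alternative="two-sided").pvalue


@dataclass
class _Pooled:
    mem: np.ndarray  # pooled membrane counts per protein
    hom: np.ndarray  # pooled homogenate counts per protein
    t_mem: float  # membrane library total
    t_hom: float  # homogenate library total


def _pool(table: SpectralCountTable, library_sizes: Mapping | None) -> _Pooled:
    mem_samples = table.samples_for(FRACTION_MEMBRANE)
    hom_samples = table.samples_for(FRACTION_HOMOGENATE)
    if not mem_samples or not hom_samples:
        raise ValidationError("need at least one sample in each fraction")
    mem = table.counts[mem_samples].sum(axis=1).to_numpy(dtype=float)
    hom = table.counts[hom_samples].sum(axis=1).to_numpy(dtype=float)
    if library_sizes is None:
        libs = table.library_sizes()
    else:
        libs = pd.Series(library_sizes, dtype=float)
    t_mem = float(libs[mem_samples].sum())
    t_hom = float(libs[hom_samples].sum())
    if t_mem <= 0 or t_hom <= 0:
        raise ValidationError("each fraction needs a positive library total")
    return _Pooled(mem, hom, t_mem, t_hom)


#: Minimum number of nonzero proteins for the median-of-proportions offset;
#: smaller tables fall back to the library-total offset.
MIN_PROTEINS_FOR_MEDIAN_OFFSET = 8


def _null_proportion(pooled: _Pooled, n: np.ndarray, library_sizes: Mapping | None) -> float:
    """Null membrane share of a protein's pooled counts.

    With explicit library sizes the offset is the membrane share of the
    library totals.  Otherwise the default is composition-robust: the median
    over proteins of the (pseudocounted) per-protein membrane proportion,
    which anchors the null on the typical protein rather than on total
    counts — membrane-capture experiments deliberately shift a large mass
    fraction, so total-count offsets would squash true enrichment and push
    unchanged proteins into apparent depletion (same rationale as
    median-of-ratios normalization in count-based differential analysis).
    """
    if library_sizes is not None:
        return pooled.t_mem / (pooled.t_mem + pooled.t_hom)
    nz = n > 0
    if nz.sum() >= MIN_PROTEINS_FOR_MEDIAN_OFFSET:
        props = (pooled.mem[nz] + PSEUDOCOUNT) / (n[nz] + 2 * PSEUDOCOUNT)
        pi0 = float(np.median(props))
        return min(max(pi0, 1e-6), 1 - 1e-6)
    return pooled.t_mem / (pooled.t_mem + pooled.t_hom)


def _dispersion(table: SpectralCountTable, library_sizes: Mapping | None) -> tuple[np.ndarray, int]:
    """Moderated per-protein Pearson dispersion from replicate residuals.

    For each protein and fraction, replicate counts are compared with their
    library-size-proportional expectation; the Pearson X²/df over both
    fractions estimates the variance inflation relative to Poisson/binomial
    sampling.  Per-protein values (df = sum of (replicates - 1)) are shrunk
    toward the experiment-wide mean with ``DISPERSION_PRIOR_DF`` prior df
    and floored at 1.  Returns (phi per protein, replicate df).
    """
    if library_sizes is None:
        libs = table.library_sizes().astype(float)
    else:
        libs = pd.Series(library_sizes, dtype=float)
    x2 = np.zeros(len(table.proteins))
    df = 0
    for fraction in (FRACTION_MEMBRANE, FRACTION_HOMOGENATE):
        samples = table.samples_for(fraction)
        if len(samples) < 2:
            continue
        c = table.counts[samples].to_numpy(dtype=float)
        w = libs[samples].to_numpy()
        w = w / w.sum()
        expected = c.sum(axis=1, keepdims=True) * w[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(expected > 0, (c - expected) ** 2 / expected, 0.0)
        x2 += contrib.sum(axis=1)
        df += len(samples) - 1
    if df == 0:
        return np.ones(len(table.proteins)), 0
    phi = x2 / df
    phi_common = float(phi.mean())
    phi_mod = (df * phi + DISPERSION_PRIOR_DF * phi_common) / (df + DISPERSION_PRIOR_DF)
    return np.maximum(phi_mod, 1.0), df


def test_enrichment(
    table: SpectralCountTable,
    lengths: Mapping[str, int] | None = None,
    alpha_q: float = 0.05,
    method: str = "auto",
    library_sizes: Mapping | None = None,
) -> list[EnrichmentResult]:
    """Per-protein membrane-vs-homogenate differential test.

    Parameters
    ----------
    table
        Spectral counts with fraction-labeled samples.
    lengths
        Protein lengths; only needed for NSAF output elsewhere — fold
        changes of a single protein are length-invariant, so this argument
        is accepted for interface symmetry and may be None.
    alpha_q
        Benjamini–Hochberg FDR threshold for the ``enriched`` call.
    method
        ``"binomial"`` (exact, assumes Poisson-like counts),
        ``"quasibinomial"`` (dispersion-inflated score test), or ``"auto"``
        (quasibinomial when between-replicate df >= 2, else binomial).
    library_sizes
        Optional per-sample library sizes overriding the observed totals
        (useful when the table holds a subset of all identified proteins).

    A protein absent from one fraction is handled by the pseudocount on the
    fold change and by the conditional test itself; nothing is dropped.
    ``enriched`` requires both ``q <= alpha_q`` and a positive log2 fold
    change.
    """
    pooled = _pool(table, library_sizes)
    n = pooled.mem + pooled.hom
    pi0 = _null_proportion(pooled, n, library_sizes)

    if method == "auto":
        _, rep_df = _dispersion(table, library_sizes)
        method = "quasibinomial" if rep_df >= 2 else "binomial"

    if method == "binomial":
        pvals = np.array(
            [_binom_p_two_sided(k, tot, pi0) for k, tot in zip(pooled.mem, n)]
        )
    elif method == "quasibinomial":
        phi, rep_df = _dispersion(table, library_sizes)
        if rep_df == 0:
            logger.warning("no replicate df for dispersion; falling back to binomial")
            pvals = np.array(
                [_binom_p_two_sided(k, tot, pi0) for k, tot in zip(pooled.mem, n)]
            )
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                z2 = (pooled.mem - n * pi0) ** 2 / (n * pi0 * (1 - pi0))
            z2 = np.where(n > 0, z2, 0.0)
            pvals = stats.chi2.sf(z2 / phi, df=1)
            pvals = np.where(n > 0, pvals, 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")

    # NSAF-scale fold change: offset-normalized pooled rates with pseudocount
    log2fc = np.log2(
        (pooled.mem + PSEUDOCOUNT) / (pooled.hom + PSEUDOCOUNT)
    ) - np.log2(pi0 / (1 - pi0))

    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(
            protein=p,
            log2_fold_change=float(fc),
            p_value=float(pv),
            fdr_q=float(qv),
            enriched=bool(qv <= alpha_q and fc > 0),
        )
        for p, fc, pv, qv in zip(table.proteins, log2fc, pvals, qvals)
    ]
    n_enriched = sum(r.enriched for r in results)
    logger.info(
        "enrichment (%s): %d/%d proteins at q <= %g", method, n_enriched, len(results), alpha_q
    )
    return results


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein": [r.protein for r in results],
            "log2fc": [r.log2_fold_change for r in results],
            "p": [r.p_value for r in results],
            "q": [r.fdr_q for r in results],
            "enriched": [r.enriched for r in results],
        }
    )
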