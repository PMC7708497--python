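"""Control-vs-disease expression comparison: one-way ANOVA with post hoc
Tukey multiple comparison, and direction-of-change reporting.

Inputs are GEO-profile style tables of normalized hybridization signals,
one control group plus one or more disease groups of 3-5 biologically
independent measurements each.  Tukey adjusted p-values come from the
studentized-range distribution (Tukey-Kramer for unequal group sizes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ValidationError


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    mean_diff: float  # mean(b) - mean(a)
    adjusted_p: float
    significant: bool
    stars: str


def _check_groups(groups: dict) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        if len(arr) < 2:
            raise ValidationError(f"group {name!r} has < 2 values")
        if not np.isfinite(arr).all():
            raise ValidationError(f"group {name!r} has non-finite values")
        out[str(name)] = arr
    return out


def anova_oneway(groups: dict) -> AnovaResult:
    """Classical one-way ANOVA over named groups.

    With zero between- and zero within-group variance the F statistic is
    undefined and reported as NaN with p = 1.
    """
    g = _check_groups(groups)
    arrays = list(g.values())
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    df_between, df_within = k - 1, n - k
    grand = np.concatenate(arrays).mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw == 0 and ssb == 0:
        return AnovaResult(float("nan"), 1.0, df_between, df_within)
    if ssw == 0:
        return AnovaResult(float("inf"), 0.0, df_between, df_within)
    f = (ssb / df_between) / (ssw / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), p, df_between, df_within)


def tukey_hsd(groups: dict, alpha: float = 0.05) -> list[PairwiseResult]:
    """All-pairs Tukey honestly-significant-difference comparison.

    Adjusted p-values use the studentized-range distribution with the
    Tukey-Kramer allowance for unequal group sizes.  Stars mirror the usual
    figure convention: ``*`` p < 0.05, ``**`` p < 0.01.
    """
    g = _check_groups(groups)
    names = list(g)
    arrays = [g[name] for name in names]
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw == 0:
        # degenerate: no within-group variance; identical groups get p = 1
        out = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                diff = float(arrays[j].mean() - arrays[i].mean())
                p = 1.0 if diff == 0 else 0.0
                out.append(
                    PairwiseResult(
                        names[i], names[j], diff, p, p < alpha, _stars(p)
                    )
                )
        return out
    res = stats.tukey_hsd(*arrays)
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            diff = float(arrays[j].mean() - arrays[i].mean())
            p = float(res.pvalue[i, j])
            out.append(
                PairwiseResult(
                    group_a=names[i],
                    group_b=names[j],
                    mean_diff=diff,
                    adjusted_p=p,
                    significant=p < alpha,
                    stars=_stars(p),
                )
            )
    return out


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def direction_table(
    groups: dict, control_label: str, epsilon: float = 0.0
) -> dict[str, str]:
    """Direction of change of each non-control group vs the control mean.

    ``up`` / ``down`` by the sign of the mean difference; ``unchanged`` when
    the absolute difference does not exceed ``epsilon``.
    """
    g = _check_groups(groups)
    if control_label not in g:
        raise ValidationError(f"control group {control_label!r} not present")
    control = g[control_label].mean()
    out = {}
    for name, arr in g.items():
        if name == control_label:
            continue
        diff = arr.mean() - control
        if abs(diff) <= epsilon:
            out[name] = "unchanged"
        else:
            out[name] = "up" if diff > 0 else "down"
    return out


def compare_gene_table(
    table: pd.DataFrame, control_label: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Run ANOVA + Tukey per gene on a long table (gene, group, value).

    Returns one row per (gene, pair) with the mean difference, adjusted p,
    stars, and the direction vs control.
    """
    for col in ("gene", "group", "value"):
        if col not in table.columns:
            raise ValidationError(f"long table missing column '{col}'")
    rows = []
    for gene, sub in table.groupby("gene", sort=True):
        groups = {
            name: vals["value"].to_numpy() for name, vals in sub.groupby("group", sort=True)
        }
        anova = anova_oneway(groups)
        directions = direction_table(groups, control_label)
        for pair in tukey_hsd(groups, alpha=alpha):
            other = pair.group_b if pair.group_a == control_label else pair.group_a
            rows.append(
                {
                    "gene": gene,
                    "pair": f"{pair.group_a} vs {pair.group_b}",
                    "mean_diff": pair.mean_diff,
                    "anova_p": anova.p_value,
                    "p_adj": pair.adjusted_p,
                    "stars": pair.stars,
                    "direction": directions.get(other, ""),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "pair", "mean_diff", "anova_p", "p_adj", "stars", "direction"],
    )
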