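"""One-to-one orthologue mapping and identifier amalgamation.

Cross-species conservation is a prioritization criterion: only clusters
where a human accession pairs with exactly one mouse accession (and vice
versa) within the supplied pair table survive.  Orthology degree is computed
on the pair table restricted to the input protein lists, so pairs touching
proteins never identified do not disqualify a cluster.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .types import OrthoCluster, ProteinRecord, ValidationError

logger = logging.getLogger(__name__)


def default_merge_map() -> dict[str, str]:
    """The shipped accession merge map (five duplicate-identifier pairs).

    Maps the superseded accession to the accession it is amalgamated into.
    """
    text = (
        resources.files("cardiomembrane").joinpath("data/default_merge_map.tsv").read_text()
    )
    out: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if line.strip():
            src, dst, _gene = line.split("\t")
            out[src] = dst
    return out


def read_merge_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["from_accession"], df["to_accession"]))


def map_one_to_one(
    human: Iterable[ProteinRecord],
    mouse: Iterable[ProteinRecord],
    pairs: Iterable[tuple[str, str]],
    restrict_to_inputs: bool = True,
) -> list[OrthoCluster]:
    """Build one-to-one orthologue clusters from an accession pair table.

    Pairs referencing accessions absent from the inputs are logged and
    skipped.  Any accession participating in more than one retained pair
    (one-to-many or many-to-one orthology) disqualifies all its pairs.
    Output is sorted by gene symbol then human accession.

    With ``restrict_to_inputs=False`` the orthology degree is computed on
    the full pair table before dropping orphan pairs, so genome-wide
    one-to-many relations disqualify clusters even when only one partner
    was identified.
    """
    humans = {p.accession: p for p in human}
    mice = {p.accession: p for p in mouse}
    pairs = [tuple(p) for p in pairs]
    seen: set[tuple[str, str]] = set()
    unique_pairs = [p for p in pairs if not (p in seen or seen.add(p))]

    def degree_filter(pairlist):
        from collections import Counter

        h_deg = Counter(h for h, _ in pairlist)
        m_deg = Counter(m for _, m in pairlist)
        return [(h, m) for h, m in pairlist if h_deg[h] == 1 and m_deg[m] == 1]

    if restrict_to_inputs:
        present = [
            (h, m) for h, m in unique_pairs if h in humans and m in mice
        ]
        dropped = len(unique_pairs) - len(present)
        if dropped:
            logger.info("skipped %d orphan ortholog pairs", dropped)
        kept = degree_filter(present)
    else:
        kept = [
            (h, m) for h, m in degree_filter(unique_pairs) if h in humans and m in mice
        ]

    clusters = []
    for h, m in kept:
        symbol = (humans[h].gene_symbol or mice[m].gene_symbol).upper()
        if not symbol:
            logger.warning("pair (%s, %s) has no gene symbol; skipped", h, m)
            continue
        clusters.append(OrthoCluster(h, m, symbol))
    clusters.sort(key=lambda c: (c.gene_symbol, c.human_accession))
    logger.info(
        "one-to-one orthology: %d pairs in -> %d clusters out", len(unique_pairs), len(clusters)
    )
    return clusters


def amalgamate_ids(
    clusters: Iterable[OrthoCluster], merge_map: Mapping[str, str]
) -> list[OrthoCluster]:
    """Fold clusters whose accessions are superseded identifiers into their targets.

    A cluster is merged into another when any of its accessions is a
    ``merge_map`` key whose value belongs to the other cluster; the target
    cluster then carries the union of both accession sets (and hence of all
    downstream count/annotation evidence).  The output size equals the input
    size minus the number of effective merges.  Chains are followed; cycles
    are an error.
    """
    clusters = list(clusters)

    def resolve(acc: str) -> str:
        seen = set()
        while acc in merge_map:
            if acc in seen:
                raise ValidationError(f"merge map cycle involving {acc}")
            seen.add(acc)
            acc = merge_map[acc]
        return acc

    owner: dict[str, int] = {}
    for i, c in enumerate(clusters):
        for acc in c.accessions:
            owner[acc] = i

    # union-find over cluster indices
    parent = list(range(len(clusters)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    merges = 0
    for src, _dst in merge_map.items():
        if src not in owner:
            continue
        dst = resolve(src)
        if dst not in owner:
            logger.warning("merge target %s not among clusters; %s left as-is", dst, src)
            continue
        a, b = find(owner[src]), find(owner[dst])
        if a != b:
            parent[a] = b
            merges += 1

    grouped: dict[int, list[OrthoCluster]] = {}
    for i, c in enumerate(clusters):
        grouped.setdefault(find(i), []).append(c)

    out = []
    for root, members in grouped.items():
        target = clusters[root]
        accs = tuple(
            dict.fromkeys(a for m in members for a in m.accessions)
        )
        out.append(
            OrthoCluster(
                target.human_accession, target.mouse_accession, target.gene_symbol, accs
            )
        )
    out.sort(key=lambda c: (c.gene_symbol, c.human_accession))
    logger.info("amalgamation: %d clusters -> %d (%d merges)", len(clusters), len(out), merges)
    assert len(out) == len(clusters) - merges
    return out
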