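"""Linking loop architecture to transcription.

Bait regions are grouped six ways — loop status (PcG hub / Pure /
Nonloop) crossed with bait class (only-H2Aub / H2Aub-H3K27me3) — and
genes are assigned to groups by overlap with the region's fragment.
Expression-level proportions per group reproduce the repression ordering
(co-marked below only-marked, loop anchors below Nonloop regions), and
up-regulated-gene fractions are computed per mutant loop-fate cell
(Ll/Hl etc.). Differential-expression labels are inputs, never computed
here; the upstream thresholds (adjusted p < 0.05, |log2FC| >= 1) travel
as metadata.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fragments import FragmentMap
from .intervals import GeneModel, IntervalSet
from .loops import H2AUB_H3K27ME3, ONLY_H2AUB

DE_THRESHOLDS = {"padj": 0.05, "abs_log2fc": 1.0}

HUB, PURE, NONLOOP = "PcGhub", "Pure", "Nonloop"
LOOP_STATUS_PRECEDENCE = (HUB, PURE, NONLOOP)
GROUPS = tuple(
    f"{status}_{cls}"
    for status in LOOP_STATUS_PRECEDENCE
    for cls in (ONLY_H2AUB, H2AUB_H3K27ME3)
)


def bait_region_groups(
    baits: pd.DataFrame, classified_loops: pd.DataFrame
) -> pd.DataFrame:
    """Six-way grouping of bait fragments.

    A bait fragment anchoring >= 1 hub loop is PcGhub; else anchoring any
    loop makes it Pure; a bait that is no loop's anchor is Nonloop. The
    six groups are disjoint and cover every bait region.
    """
    hub = classified_loops[classified_loops["hub_member"]]
    pure = classified_loops[~classified_loops["hub_member"]]
    hub_anchors = set(hub["anchorA"]) | set(hub["anchorB"])
    pure_anchors = set(pure["anchorA"]) | set(pure["anchorB"])
    rows = []
    for fid, cls in zip(baits["fragment_id"], baits["bait_class"]):
        status = HUB if fid in hub_anchors else PURE if fid in pure_anchors else NONLOOP
        rows.append((fid, cls, status, f"{status}_{cls}"))
    return pd.DataFrame(
        rows, columns=["fragment_id", "bait_class", "loop_status", "group"]
    )


def assign_genes_to_regions(
    groups: pd.DataFrame,
    fragments: FragmentMap,
    genes: Sequence[GeneModel],
) -> pd.DataFrame:
    """Gene -> group assignment on >= 1 bp gene-body/fragment overlap.

    A gene overlapping bait fragments from several groups is assigned by
    loop-status precedence PcG hub > Pure > Nonloop (co-marked before
    only-marked within a status) so group gene sets stay disjoint.
    """
    rank = {g: i for i, g in enumerate(
        f"{status}_{cls}"
        for status in LOOP_STATUS_PRECEDENCE
        for cls in (H2AUB_H3K27ME3, ONLY_H2AUB)
    )}
    frag_group = dict(zip(groups["fragment_id"], groups["group"]))
    footprint = IntervalSet()
    owner = {}
    for fid in groups["fragment_id"]:
        iv = fragments.interval(fid)
        footprint.add(iv)
        owner[iv] = fid
    rows = []
    for gene in genes:
        hits = footprint.query(gene.interval)
        if not hits:
            continue
        candidates = sorted(
            {frag_group[owner[iv]] for iv in hits}, key=lambda g: rank[g]
        )
        rows.append((gene.gene_id, candidates[0]))
    return pd.DataFrame(rows, columns=["gene_id", "group"])


def expression_proportions(
    gene_groups: pd.DataFrame,
    expression: pd.Series,
    bin_edges: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Per-group proportions of genes across expression bins.

    Default binning is a zero bin plus quartiles of the nonzero
    expression values of the assigned genes. Proportions per group sum
    to 1. Groups with no assigned genes are omitted (warning via NaN-free
    output).
    """
    expr = expression.reindex(gene_groups["gene_id"]).to_numpy(dtype=float)
    df = gene_groups.assign(expression=expr).dropna(subset=["expression"])
    if bin_edges is None:
        nonzero = df.loc[df["expression"] > 0, "expression"]
        if nonzero.empty:
            bin_edges = [0.0, np.inf]
        else:
            qs = np.quantile(nonzero, [0.25, 0.5, 0.75])
            bin_edges = [0.0, *np.unique(qs), np.inf]
    edges = np.asarray(bin_edges, dtype=float)
    labels = ["zero"] + [f"bin{i + 1}" for i in range(len(edges) - 1)]

    def binof(x: float) -> str:
        if x <= 0:
            return "zero"
        return labels[1 + int(np.searchsorted(edges[1:-1], x, side="left"))]

    df["bin"] = [binof(x) for x in df["expression"]]
    table = (
        df.groupby(["group", "bin"], sort=False).size().unstack(fill_value=0)
    )
    table = table.reindex(columns=[l for l in labels if l in table.columns])
    props = table.div(table.sum(axis=1), axis=0)
    props.index.name = "group"
    return props


def upregulated_fraction_by_fate(
    cell_genes: Mapping[str, Sequence[str]],
    de_labels: pd.Series,
) -> pd.DataFrame:
    """Fraction of up-regulated genes per loop-fate cell.

    ``cell_genes`` maps each Ll/Hl-style cell to the gene ids at that
    cell's loop anchors; ``de_labels`` holds up/down/ns per gene. The
    fraction is up-labeled genes over labeled genes, with gene counts
    reported alongside; empty cells give NaN.
    """
    rows = []
    for cell, gene_ids in cell_genes.items():
        labels = de_labels.reindex(pd.Index(gene_ids).unique()).dropna()
        n = len(labels)
        n_up = int((labels == "up").sum())
        rows.append((cell, n, n_up, n_up / n if n else np.nan))
    return pd.DataFrame(
        rows, columns=["cell", "n_genes", "n_up", "fraction_up"]
    ).set_index("cell")


def genes_at_loop_anchors(
    loops: pd.DataFrame,
    fragments: FragmentMap,
    genes: Sequence[GeneModel],
    bait_classes: Mapping[int, str] | None = None,
) -> set[str]:
    """Gene ids whose body overlaps any (bait, by default) anchor fragment."""
    anchors: set[int] = set()
    for row in loops.itertuples():
        for a in (row.anchorA, row.anchorB):
            if bait_classes is None or a in bait_classes:
                anchors.add(a)
    footprint = IntervalSet(fragments.interval(a) for a in anchors)
    return {
        g.gene_id for g in genes if footprint.overlaps_any(g.interval)
    }
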