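"""Bait typing and five-way Polycomb loop classification with hub detection.

The capture design baits every H2Aub-enriched restriction fragment, so a
captured loop has at least one bait anchor. Baits split into *only-H2Aub*
and *H2Aub/H3K27me3* (co-marked) types; loops then classify three ways by
their bait-anchor composition (Both / only-H2Aub / H2Aub-H3K27me3), and
five ways once hub membership is resolved: the *PcG hub* is seeded by the
anchors of Both-loops, and any loop sharing an anchor fragment with that
seed set belongs to it; loops independent of the hub are *Pure*.

Loop tables are pandas DataFrames with integer fragment-id anchor columns
``anchorA``/``anchorB`` stored in canonical order (lower id — i.e. lower
genomic coordinate — first).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .fragments import FragmentMap
from .intervals import GeneModel, GenomicInterval, IntervalSet

logger = logging.getLogger(__name__)

# Bait classes
ONLY_H2AUB = "only_H2Aub"
H2AUB_H3K27ME3 = "H2Aub_H3K27me3"

# Baitness
BAIT_BAIT = "Bait-Bait"
BAIT_NONBAIT = "Bait-Nonbait"

# Three-way PcG classes
BOTH = "Both"
PCG_CLASSES = (BOTH, ONLY_H2AUB, H2AUB_H3K27ME3)

# Five-way final classes
PCGHUB_BOTH = "PcGhub_Both"
PCGHUB_ONLY_H2AUB = "PcGhub_only_H2Aub"
PCGHUB_H2AUB_H3K27ME3 = "PcGhub_H2Aub_H3K27me3"
PURE_ONLY_H2AUB = "Pure_only_H2Aub"
PURE_H2AUB_H3K27ME3 = "Pure_H2Aub_H3K27me3"
FINAL_CLASSES = (
    PCGHUB_BOTH,
    PCGHUB_ONLY_H2AUB,
    PCGHUB_H2AUB_H3K27ME3,
    PURE_ONLY_H2AUB,
    PURE_H2AUB_H3K27ME3,
)

# Interaction-caller weight parameters used by the upstream statistical loop
# caller (CHiCAGO); recorded as configuration passthrough only — statistical
# loop calling is outside this package.
CHICAGO_WEIGHTS = {
    "weightAlpha": 13.5319239,
    "weightBeta": -1.3100426,
    "weightGamma": -10.3516115,
    "weightDelta": 0.1635212,
}

# Anchor feature labels, in precedence order
FEATURE_PRECEDENCE = ("exon", "intron", "promoter", "intergenic")


def canonical_loops(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with ``anchorA < anchorB`` and a ``loop_id`` column."""
    df = df.copy()
    a = df[["anchorA", "anchorB"]].min(axis=1)
    b = df[["anchorA", "anchorB"]].max(axis=1)
    if (a == b).any():
        raise ValueError("a loop's two anchors must be distinct fragments")
    df["anchorA"], df["anchorB"] = a, b
    if "loop_id" not in df.columns:
        df.insert(0, "loop_id", [f"loop{i}" for i in range(len(df))])
    return df


def loops_from_intervals(
    table: pd.DataFrame, fragments: FragmentMap
) -> pd.DataFrame:
    """Convert a BEDPE-like anchor-interval table to fragment-id anchors.

    Each anchor interval is assigned the fragment containing its midpoint.
    """
    rows = []
    for _, r in table.iterrows():
        fa = fragments.containing(r["chromA"], (int(r["startA"]) + int(r["endA"])) // 2)
        fb = fragments.containing(r["chromB"], (int(r["startB"]) + int(r["endB"])) // 2)
        rows.append((fa, fb, r.get("score", np.nan)))
    return canonical_loops(
        pd.DataFrame(rows, columns=["anchorA", "anchorB", "score"])
    )


# ---------------------------------------------------------------------------
# Bait typing


def type_baits(
    bait_fragment_ids: Sequence[int],
    fragments: FragmentMap,
    k27_peaks: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """Two-way partition of bait fragments by H3K27me3 co-marking.

    A bait fragment overlapping >= 1 H3K27me3 peak is typed
    ``H2Aub_H3K27me3``; otherwise ``only_H2Aub``.
    """
    peaks = IntervalSet(k27_peaks)
    records = [
        (
            fid,
            H2AUB_H3K27ME3
            if peaks.overlaps_any(fragments.interval(fid))
            else ONLY_H2AUB,
        )
        for fid in sorted(bait_fragment_ids)
    ]
    return pd.DataFrame(records, columns=["fragment_id", "bait_class"])


def bait_class_map(baits: pd.DataFrame) -> dict[int, str]:
    return dict(zip(baits["fragment_id"], baits["bait_class"]))


# ---------------------------------------------------------------------------
# Loop classification


def classify_baitness(
    loops: pd.DataFrame, bait_classes: Mapping[int, str]
) -> tuple[pd.DataFrame, int]:
    """Assign Bait-Bait / Bait-Nonbait; drop zero-bait loops.

    A loop with no bait anchor cannot have been captured by the probe
    design, so such records are removed and counted.
    """
    loops = canonical_loops(loops)
    is_bait_a = loops["anchorA"].isin(bait_classes)
    is_bait_b = loops["anchorB"].isin(bait_classes)
    n_bait = is_bait_a.astype(int) + is_bait_b.astype(int)
    n_dropped = int((n_bait == 0).sum())
    if n_dropped:
        logger.info("dropped %d loops with no bait anchor", n_dropped)
    loops = loops[n_bait > 0].copy()
    loops["baitness"] = np.where(
        n_bait[n_bait > 0] == 2, BAIT_BAIT, BAIT_NONBAIT
    )
    return loops.reset_index(drop=True), n_dropped


def classify_pcg(
    loops: pd.DataFrame,
    bait_classes: Mapping[int, str],
    nonbait_k27: set[int] | None = None,
) -> pd.DataFrame:
    """Three-way PcG classification from bait-anchor composition.

    * ``Both`` — one anchor is an only-H2Aub bait and the other an
      H2Aub/H3K27me3 bait;
    * ``only_H2Aub`` — every bait anchor is only-H2Aub and no anchor is a
      co-marked bait;
    * ``H2Aub_H3K27me3`` — >= 1 bait anchor co-marked, no only-H2Aub bait
      anchor.

    ``nonbait_k27`` optionally supplies non-bait anchor fragments that
    overlap an H3K27me3 peak: a Bait-Nonbait loop whose non-bait anchor is
    in that set is classed ``H2Aub_H3K27me3`` ("at least one anchor is an
    H3K27me3-enriched region") and flagged in the ``nonbait_k27`` column
    for transparency.
    """
    if "baitness" not in loops.columns:
        raise ValueError("run classify_baitness first")
    loops = loops.copy()
    classes = []
    flags = []
    for a, b in zip(loops["anchorA"], loops["anchorB"]):
        ca, cb = bait_classes.get(a), bait_classes.get(b)
        bait_set = {c for c in (ca, cb) if c is not None}
        flag = False
        if len(bait_set) == 2:
            cls = BOTH
        elif bait_set == {H2AUB_H3K27ME3}:
            cls = H2AUB_H3K27ME3
        else:  # bait anchors all only-H2Aub
            cls = ONLY_H2AUB
            if nonbait_k27:
                nonbait = b if ca is not None and cb is None else (
                    a if cb is not None and ca is None else None
                )
                if nonbait is not None and nonbait in nonbait_k27:
                    cls = H2AUB_H3K27ME3
                    flag = True
        classes.append(cls)
        flags.append(flag)
    loops["pcg_class"] = classes
    loops["nonbait_k27"] = flags
    return loops


def detect_pcg_hub(
    loops: pd.DataFrame,
    transitive: bool = False,
    bait_anchors_only: bool = False,
    bait_classes: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Resolve hub membership and the five-way final class.

    The seed anchor set is every anchor of a Both-loop. A non-Both loop is
    a hub member iff it shares >= 1 anchor fragment with the seed set —
    one-step sharing, the literal reading of a hub "started with" Both-loop
    anchors. ``transitive=True`` instead takes full connected components of
    the anchor-sharing graph that contain a Both-loop.
    ``bait_anchors_only=True`` restricts the sharing test to the loop's
    bait anchors (requires ``bait_classes``).

    Both-loops always have ``hub_member=True`` and final class
    ``PcGhub_Both``; the five final classes partition the table.
    """
    if "pcg_class" not in loops.columns:
        raise ValueError("run classify_pcg first")
    loops = loops.copy()
    both = loops["pcg_class"] == BOTH
    seed = set(loops.loc[both, "anchorA"]) | set(loops.loc[both, "anchorB"])

    if transitive:
        graph = nx.Graph()
        graph.add_edges_from(zip(loops["anchorA"], loops["anchorB"]))
        hub_nodes: set[int] = set()
        for comp in nx.connected_components(graph):
            if comp & seed:
                hub_nodes |= comp
        member = loops["anchorA"].isin(hub_nodes) | loops["anchorB"].isin(hub_nodes)
    else:
        if bait_anchors_only:
            if bait_classes is None:
                raise ValueError("bait_anchors_only requires bait_classes")
            share_a = loops["anchorA"].isin(seed) & loops["anchorA"].isin(bait_classes)
            share_b = loops["anchorB"].isin(seed) & loops["anchorB"].isin(bait_classes)
            member = share_a | share_b
        else:
            member = loops["anchorA"].isin(seed) | loops["anchorB"].isin(seed)
    loops["hub_member"] = member | both

    final = {
        (BOTH, True): PCGHUB_BOTH,
        (ONLY_H2AUB, True): PCGHUB_ONLY_H2AUB,
        (ONLY_H2AUB, False): PURE_ONLY_H2AUB,
        (H2AUB_H3K27ME3, True): PCGHUB_H2AUB_H3K27ME3,
        (H2AUB_H3K27ME3, False): PURE_H2AUB_H3K27ME3,
    }
    loops["final_class"] = [
        final[(c, bool(h))] for c, h in zip(loops["pcg_class"], loops["hub_member"])
    ]
    return loops


def classify_loops(
    loops: pd.DataFrame,
    bait_classes: Mapping[int, str],
    nonbait_k27: set[int] | None = None,
    transitive: bool = False,
    bait_anchors_only: bool = False,
) -> tuple[pd.DataFrame, int]:
    """Full chain: baitness -> PcG class -> hub membership/final class."""
    classified, n_dropped = classify_baitness(loops, bait_classes)
    classified = classify_pcg(classified, bait_classes, nonbait_k27)
    classified = detect_pcg_hub(
        classified, transitive=transitive,
        bait_anchors_only=bait_anchors_only, bait_classes=bait_classes,
    )
    return classified, n_dropped


# ---------------------------------------------------------------------------
# Geometry


def loop_lengths(loops: pd.DataFrame, fragments: FragmentMap) -> pd.Series:
    """Midpoint-to-midpoint genomic distance per loop.

    Trans-chromosomal pairs get NaN (flagged, excluded from length stats).
    """
    out = np.full(len(loops), np.nan)
    for i, (a, b) in enumerate(zip(loops["anchorA"], loops["anchorB"])):
        if fragments.chrom_of(a) == fragments.chrom_of(b):
            out[i] = abs(fragments.midpoint(a) - fragments.midpoint(b))
    return pd.Series(out, index=loops.index, name="loop_length")


def gene_loop_span(
    loops: pd.DataFrame,
    gene: GeneModel,
    fragments: FragmentMap,
    from_gene: bool = False,
) -> dict[str, int] | None:
    """Per-side span of the loops anchored on one gene.

    For every loop with an anchor fragment overlapping the gene body, the
    *other* anchor midpoints are split by genomic side (left/right of the
    gene). Span per side is the maximum pairwise distance among that
    side's midpoints (0 for a single anchor); ``from_gene=True`` measures
    instead the maximum distance from the nearest gene edge. A smaller
    span means more concentrated interactions. Returns None when fewer
    than two loops are anchored on the gene.
    """
    giv = gene.interval
    others: list[int] = []
    for a, b in zip(loops["anchorA"], loops["anchorB"]):
        for on_gene, other in ((a, b), (b, a)):
            iv = fragments.interval(on_gene)
            if iv.chrom == giv.chrom and iv.start < giv.end and giv.start < iv.end:
                if fragments.chrom_of(other) == giv.chrom:
                    others.append(fragments.midpoint(other))
                break
    if len(others) < 2:
        return None
    sides = {
        "left-anchor": [m for m in others if m < giv.start],
        "right-anchor": [m for m in others if m >= giv.end],
    }
    spans: dict[str, int] = {}
    for side, mids in sides.items():
        if not mids:
            continue
        if from_gene:
            edge = giv.start if side == "left-anchor" else giv.end
            spans[side] = max(abs(m - edge) for m in mids)
        else:
            spans[side] = max(mids) - min(mids)
    return spans


# ---------------------------------------------------------------------------
# Anchor annotation


def annotate_anchor_features(
    anchor_ids: Sequence[int],
    fragments: FragmentMap,
    genes: Sequence[GeneModel],
) -> pd.Series:
    """Label each anchor fragment exon/intron/promoter/intergenic.

    Precedence exon > intron > promoter > intergenic on >= 1 bp overlap;
    promoter windows come from the gene models (default 1 kb upstream).
    """
    exons = IntervalSet()
    introns = IntervalSet()
    promoters = IntervalSet()
    for gene in genes:
        for ex in gene.exons:
            exons.add(ex)
        for intr in gene.introns():
            introns.add(intr)
        if not gene.exons:
            introns.add(gene.interval)  # featureless gene body counts as intron
        prom = gene.promoter()
        if prom is not None:
            promoters.add(prom)

    labels = []
    for fid in anchor_ids:
        iv = fragments.interval(fid)
        if exons.overlaps_any(iv):
            labels.append("exon")
        elif introns.overlaps_any(iv):
            labels.append("intron")
        elif promoters.overlaps_any(iv):
            labels.append("promoter")
        else:
            labels.append("intergenic")
    return pd.Series(labels, index=list(anchor_ids), name="feature")


def feature_distribution(labels_by_group: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Per-group proportions over the four anchor feature labels."""
    rows = {}
    for group, labels in labels_by_group.items():
        counts = labels.value_counts()
        rows[group] = [
            counts.get(f, 0) / len(labels) if len(labels) else np.nan
            for f in FEATURE_PRECEDENCE
        ]
    return pd.DataFrame(rows, index=list(FEATURE_PRECEDENCE)).T


# ---------------------------------------------------------------------------
# Summaries


def bait_anchor_venn(loops: pd.DataFrame, bait_classes: Mapping[int, str]) -> dict:
    """Bait-anchor overlap between Bait-Bait and Bait-Nonbait loops.

    Returns counts of bait anchors exclusive to each baitness class and
    shared between them (a Venn over anchor fragments).
    """
    bb = loops["baitness"] == BAIT_BAIT
    anchors_bb = set(loops.loc[bb, "anchorA"]) | set(loops.loc[bb, "anchorB"])
    anchors_bn_all = set(loops.loc[~bb, "anchorA"]) | set(loops.loc[~bb, "anchorB"])
    anchors_bb &= set(bait_classes)
    anchors_bn = anchors_bn_all & set(bait_classes)
    return {
        "bait_bait_only": len(anchors_bb - anchors_bn),
        "bait_nonbait_only": len(anchors_bn - anchors_bb),
        "shared": len(anchors_bb & anchors_bn),
    }


def class_summary(loops: pd.DataFrame) -> dict:
    """Headline counts and proportions for a classified loop table."""
    n = len(loops)
    summary: dict = {"n_loops": n}
    for col in ("baitness", "pcg_class", "final_class"):
        if col in loops.columns:
            counts = loops[col].value_counts().to_dict()
            summary[col] = {k: int(v) for k, v in counts.items()}
            summary[f"{col}_pct"] = {
                k: round(100.0 * v / n, 2) for k, v in counts.items()
            } if n else {}
    if "hub_member" in loops.columns and n:
        summary["hub_pct"] = round(100.0 * float(loops["hub_member"].mean()), 2)
    return summary
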