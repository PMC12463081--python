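"""Wild-type vs PRC1-mutant comparison of loops and histone marks.

WT loops are matched against mutant loops on canonical anchor-fragment
pairs, giving disappeared / maintained / newly-formed sets. Each WT loop
is then cross-classified by loop fate (Ll lost / Lm maintained) and by
histone-modification fate at its bait anchors (Hl lost / Hm maintained),
and the 2x2 association is tested with a Pearson chi-squared statistic.
Newly formed loops are characterized by baitness and by their brand-new
non-bait anchors, which feed the occupancy-enrichment stage.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import FragmentMap
from .loops import BAIT_BAIT, BAIT_NONBAIT, ONLY_H2AUB, canonical_loops
from .signal import SignalTrack

logger = logging.getLogger(__name__)

H2AUB_MARK = "H2Aub"
K27_MARK = "H3K27me3"

LOOP_LOST, LOOP_MAINTAINED = "Ll", "Lm"
HM_LOST, HM_MAINTAINED = "Hl", "Hm"
FATE_CELLS = ("Ll/Hl", "Lm/Hl", "Ll/Hm", "Lm/Hm")

# Differential-binding decrease threshold on |log2(mutant/WT)|
DEFAULT_LOG2_THRESHOLD = 0.2


def _pair_index(loops: pd.DataFrame) -> pd.MultiIndex:
    return pd.MultiIndex.from_arrays([loops["anchorA"], loops["anchorB"]])


def match_loops(
    wt_loops: pd.DataFrame, mut_loops: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Exact set algebra on canonical anchor pairs.

    Returns ``disappeared`` (WT only), ``maintained`` (both) and ``new``
    (mutant only). Conservation holds by construction:
    ``|disappeared| + |maintained| == |WT|`` and
    ``|new| + |maintained| == |mutant|``.
    """
    wt = canonical_loops(wt_loops)
    mut = canonical_loops(mut_loops)
    wt_pairs = _pair_index(wt)
    mut_pairs = _pair_index(mut)
    in_mut = wt_pairs.isin(mut_pairs)
    in_wt = mut_pairs.isin(wt_pairs)
    return {
        "disappeared": wt[~in_mut].reset_index(drop=True),
        "maintained": wt[in_mut].reset_index(drop=True),
        "new": mut[~in_wt].reset_index(drop=True),
    }


def loop_fates(wt_loops: pd.DataFrame, mut_loops: pd.DataFrame) -> pd.Series:
    """Ll/Lm per WT loop (index aligned with the canonical WT table)."""
    wt = canonical_loops(wt_loops)
    present = _pair_index(wt).isin(_pair_index(canonical_loops(mut_loops)))
    return pd.Series(
        np.where(present, LOOP_MAINTAINED, LOOP_LOST), index=wt.index, name="loop_fate"
    )


# ---------------------------------------------------------------------------
# Histone-modification change


def compute_hm_changes(
    fragment_ids: Sequence[int],
    fragments: FragmentMap,
    wt_track: SignalTrack,
    mut_track: SignalTrack,
    mark: str,
    log2_threshold: float = DEFAULT_LOG2_THRESHOLD,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Mutant/WT occupancy ratio per fragment with a decrease call.

    ``decreased`` is true when ``log2(ratio) < -log2_threshold`` — the
    differential-binding convention of an absolute log2 fold change above
    the threshold, with the decreasing sign. A pseudocount (default 1e-3
    of the WT genome-wide mean) keeps ratios finite at uncovered
    fragments.
    """
    if pseudocount is None:
        base = wt_track.genome_wide_mean()
        pseudocount = 1e-3 * base if base > 0 else 1e-9
    rows = []
    for fid in fragment_ids:
        iv = fragments.interval(fid)
        wt_occ = wt_track.region_mean(iv)
        mut_occ = mut_track.region_mean(iv)
        ratio = (mut_occ + pseudocount) / (wt_occ + pseudocount)
        rows.append(
            (fid, mark, ratio, bool(np.log2(ratio) < -log2_threshold))
        )
    return pd.DataFrame(rows, columns=["fragment_id", "mark", "ratio", "decreased"])


def hm_changes_from_bed(
    fragment_ids: Sequence[int],
    fragments: FragmentMap,
    decreased_regions: Sequence,
    mark: str,
) -> pd.DataFrame:
    """Decrease calls from a supplied differential-region list (overrides
    computed ratio thresholds when an external differential-binding caller
    has been run)."""
    from .intervals import IntervalSet

    regions = IntervalSet(decreased_regions)
    rows = [
        (fid, mark, np.nan, regions.overlaps_any(fragments.interval(fid)))
        for fid in fragment_ids
    ]
    return pd.DataFrame(rows, columns=["fragment_id", "mark", "ratio", "decreased"])


def _decrease_lookup(hm_changes: pd.DataFrame) -> dict[tuple[int, str], bool]:
    return {
        (int(r.fragment_id), r.mark): bool(r.decreased)
        for r in hm_changes.itertuples()
    }


def hm_fates(
    loops: pd.DataFrame,
    hm_changes: pd.DataFrame,
    bait_classes: Mapping[int, str],
    both_anchors: bool = False,
    include_nonbait: bool = False,
) -> pd.Series:
    """Hl/Hm per loop from anchor-level decrease calls.

    Mark relevance follows the loop's PcG class: for only-H2Aub loops only
    an H2Aub decrease counts; for H3K27me3-involved loops a decrease of
    either mark counts. By default Hl requires >= 1 affected *bait* anchor
    (``both_anchors=True`` demands every consulted anchor be affected;
    ``include_nonbait=True`` consults non-bait anchors too). Anchors with
    no change record are treated as maintained, with a warning.
    """
    lookup = _decrease_lookup(hm_changes)
    missing = 0
    fates = []
    for row in loops.itertuples():
        marks = (
            (H2AUB_MARK,)
            if getattr(row, "pcg_class", None) == ONLY_H2AUB
            else (H2AUB_MARK, K27_MARK)
        )
        anchors = [
            a
            for a in (row.anchorA, row.anchorB)
            if include_nonbait or a in bait_classes
        ]
        flags = []
        for anchor in anchors:
            hits = [lookup.get((anchor, m)) for m in marks]
            known = [h for h in hits if h is not None]
            if not known:
                missing += 1
                flags.append(False)  # no data -> treated as maintained
            else:
                flags.append(any(known))
        affected = all(flags) if both_anchors and flags else any(flags)
        fates.append(HM_LOST if affected else HM_MAINTAINED)
    if missing:
        logger.warning(
            "%d anchors had no HM change record; treated as maintained", missing
        )
    return pd.Series(fates, index=loops.index, name="hm_fate")


# ---------------------------------------------------------------------------
# Cross-classification and association


def cross_classify(loop_fate: pd.Series, hm_fate: pd.Series) -> pd.DataFrame:
    """Counts and proportions of the four Ll/Hl cells over WT loops."""
    cells = loop_fate.str.cat(hm_fate, sep="/")
    counts = cells.value_counts().reindex(FATE_CELLS, fill_value=0)
    out = counts.rename("count").to_frame()
    total = int(counts.sum())
    out["proportion"] = counts / total if total else np.nan
    out.index.name = "cell"
    return out


def fate_table(loop_fate: pd.Series, hm_fate: pd.Series) -> np.ndarray:
    """2x2 contingency table [[lost&Hl, lost&Hm], [maint&Hl, maint&Hm]]."""
    ll = loop_fate == LOOP_LOST
    hl = hm_fate == HM_LOST
    return np.array(
        [
            [int((ll & hl).sum()), int((ll & ~hl).sum())],
            [int((~ll & hl).sum()), int((~ll & ~hl).sum())],
        ]
    )


def association_test(table: np.ndarray, yates: bool = False) -> dict:
    """Pearson chi-squared on a 2x2 table, plus an odds ratio.

    No continuity correction by default (configurable). The odds ratio
    applies a Haldane-Anscombe 0.5 correction when any cell is zero. A
    zero marginal leaves the test undefined (``degenerate=True``,
    p-value NaN).
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("association_test needs a nonnegative 2x2 table")
    if table.sum() == 0:
        raise ValueError("empty contingency table")
    degenerate = bool(
        (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
    )
    if degenerate:
        statistic, p_value = np.nan, np.nan
    else:
        statistic, p_value, _dof, _exp = stats.chi2_contingency(
            table, correction=yates
        )
    t = table + 0.5 if (table == 0).any() else table
    odds_ratio = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return {
        "statistic": float(statistic),
        "p_value": float(p_value),
        "odds_ratio": float(odds_ratio),
        "degenerate": degenerate,
    }


# ---------------------------------------------------------------------------
# Newly formed loops


def characterize_new_loops(
    new_loops: pd.DataFrame,
    wt_bait_classes: Mapping[int, str],
    wt_anchor_ids: set[int],
) -> dict:
    """Baitness proportions of new loops and their brand-new anchors.

    A *new non-bait anchor* is an anchor of a newly formed loop that is
    neither a WT bait nor any WT loop's anchor; the set is split by the
    bait class of the partner anchor, feeding the occupancy-enrichment
    stage.
    """
    baitness = []
    new_nonbait: dict[str, set[int]] = {ONLY_H2AUB: set(), "H2Aub_H3K27me3": set()}
    for row in new_loops.itertuples():
        a, b = row.anchorA, row.anchorB
        n_bait = (a in wt_bait_classes) + (b in wt_bait_classes)
        baitness.append(BAIT_BAIT if n_bait == 2 else BAIT_NONBAIT if n_bait else "none")
        for anchor, partner in ((a, b), (b, a)):
            if anchor not in wt_bait_classes and anchor not in wt_anchor_ids:
                partner_class = wt_bait_classes.get(partner)
                if partner_class is not None:
                    new_nonbait[partner_class].add(anchor)
    counts = pd.Series(baitness).value_counts()
    n = len(new_loops)
    return {
        "baitness_counts": {k: int(v) for k, v in counts.items()},
        "baitness_pct": {k: round(100.0 * v / n, 2) for k, v in counts.items()}
        if n
        else {},
        "new_nonbait_anchors": {k: sorted(v) for k, v in new_nonbait.items()},
    }


def anchor_venn(
    matched: Mapping[str, pd.DataFrame], bait_ids: set[int]
) -> dict[str, int]:
    """Three-way Venn of bait anchors across disappeared/maintained/new loops."""
    sets = {}
    for key in ("disappeared", "maintained", "new"):
        df = matched[key]
        anchors = set(df["anchorA"]) | set(df["anchorB"])
        sets[key] = anchors & bait_ids
    d, m, n = sets["disappeared"], sets["maintained"], sets["new"]
    return {
        "disappeared_only": len(d - m - n),
        "maintained_only": len(m - d - n),
        "new_only": len(n - d - m),
        "disappeared_maintained": len((d & m) - n),
        "disappeared_new": len((d & n) - m),
        "maintained_new": len((m & n) - d),
        "all_three": len(d & m & n),
    }
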