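"""Loop matching, fate cross-classification and association testing."""

import numpy as np
import pandas as pd
import pytest

from pcgloop.loops import H2AUB_H3K27ME3, ONLY_H2AUB
from pcgloop.mutant import (
    H2AUB_MARK,
    K27_MARK,
    anchor_venn,
    association_test,
    characterize_new_loops,
    cross_classify,
    fate_table,
    hm_fates,
    loop_fates,
    match_loops,
)
from pcgloop.synthetic import simulate_loop_fates


def loops_df(pairs):
    df = pd.DataFrame(pairs, columns=["anchorA", "anchorB"])
    df["score"] = 1.0
    return df


def changes_df(rows):
    return pd.DataFrame(rows, columns=["fragment_id", "mark", "ratio", "decreased"])


class TestMatchLoops:
    def test_set_algebra(self):
        out = match_loops(loops_df([(1, 2), (3, 4)]), loops_df([(3, 4), (5, 6)]))
        assert [(r.anchorA, r.anchorB) for r in out["disappeared"].itertuples()] == [(1, 2)]
        assert [(r.anchorA, r.anchorB) for r in out["maintained"].itertuples()] == [(3, 4)]
        assert [(r.anchorA, r.anchorB) for r in out["new"].itertuples()] == [(5, 6)]

    def test_identical_sets(self):
        out = match_loops(loops_df([(1, 2)]), loops_df([(2, 1)]))  # canonical match
        assert len(out["disappeared"]) == 0 and len(out["new"]) == 0

    def test_empty_mutant_all_disappear(self):
        out = match_loops(loops_df([(1, 2), (3, 4)]), loops_df([]).assign(anchorA=[], anchorB=[]))
        assert len(out["disappeared"]) == 2

    def test_conservation(self, default_sim):
        out = match_loops(default_sim.loops_wt, default_sim.loops_mut)
        assert len(out["disappeared"]) + len(out["maintained"]) == len(default_sim.loops_wt)
        assert len(out["new"]) + len(out["maintained"]) == len(default_sim.loops_mut)


class TestHmFates:
    CLASSES = {1: ONLY_H2AUB, 2: ONLY_H2AUB, 3: H2AUB_H3K27ME3}

    def fates(self, pairs, changes, pcg, **kw):
        df = loops_df(pairs)
        df["pcg_class"] = pcg
        return hm_fates(df, changes, self.CLASSES, **kw)

    def test_one_affected_anchor_suffices(self):
        ch = changes_df([(1, H2AUB_MARK, 0.4, True), (2, H2AUB_MARK, 1.0, False)])
        assert self.fates([(1, 2)], ch, ONLY_H2AUB).tolist() == ["Hl"]

    def test_neither_decreased(self):
        ch = changes_df([(1, H2AUB_MARK, 1.0, False), (2, H2AUB_MARK, 1.0, False)])
        assert self.fates([(1, 2)], ch, ONLY_H2AUB).tolist() == ["Hm"]

    def test_missing_data_defaults_to_maintained(self, caplog):
        assert self.fates([(1, 2)], changes_df([]), ONLY_H2AUB).tolist() == ["Hm"]
        assert any("no HM change record" in r.message for r in caplog.records)

    def test_mark_relevance_only_h2aub_ignores_k27(self):
        ch = changes_df([(1, K27_MARK, 0.4, True), (1, H2AUB_MARK, 1.0, False)])
        assert self.fates([(1, 2)], ch, ONLY_H2AUB).tolist() == ["Hm"]
        # a K27-involved loop consults both marks
        assert self.fates([(3, 9)], changes_df(
            [(3, K27_MARK, 0.4, True), (3, H2AUB_MARK, 1.0, False)]
        ), H2AUB_H3K27ME3).tolist() == ["Hl"]

    def test_both_anchors_mode(self):
        ch = changes_df([(1, H2AUB_MARK, 0.4, True), (2, H2AUB_MARK, 1.0, False)])
        assert self.fates([(1, 2)], ch, ONLY_H2AUB, both_anchors=True).tolist() == ["Hm"]

    def test_threshold_monotonicity(self, default_sim, default_classified):
        """Lowering the decrease threshold never converts Hl to Hm."""
        from pcgloop.mutant import compute_hm_changes

        sim = default_sim
        classes = default_classified["classes"]
        loops = default_classified["loops"].head(100)
        fids = sorted(set(loops["anchorA"]) | set(loops["anchorB"]) & set(classes))
        fids = [f for f in fids if f in classes]
        strict, loose = [
            hm_fates(
                loops,
                compute_hm_changes(
                    fids, sim.fragments, sim.tracks["h2aub_wt"],
                    sim.tracks["h2aub_mut"], H2AUB_MARK, log2_threshold=thr,
                ),
                classes,
            )
            for thr in (0.5, 0.1)
        ]
        assert not ((strict == "Hl") & (loose == "Hm")).any()


class TestCrossClassify:
    def test_uniform_cells(self):
        lf = pd.Series(["Ll", "Lm", "Ll", "Lm"])
        hf = pd.Series(["Hl", "Hl", "Hm", "Hm"])
        out = cross_classify(lf, hf)
        assert (out["proportion"] == 0.25).all()
        assert out["count"].sum() == 4

    def test_degenerate_single_cell(self):
        lf = pd.Series(["Lm"] * 5)
        hf = pd.Series(["Hm"] * 5)
        out = cross_classify(lf, hf)
        assert out.loc["Lm/Hm", "proportion"] == 1.0
        assert abs(out["proportion"].sum() - 1.0) < 1e-12

    def test_coupled_simulation_modal_cell(self, rng):
        # HM loss prevalence 0.6 with strong coupling: E[Ll/Hl] = 0.48
        # dominates every other cell
        fates = simulate_loop_fates(2000, 0.6, 0.8, 0.2, rng)
        out = cross_classify(fates["loop_fate"], fates["hm_fate"])
        assert out["count"].idxmax() == "Ll/Hl"


class TestAssociationTest:
    def test_closed_form_statistic(self):
        res = association_test(np.array([[30, 10], [10, 30]]))
        assert res["statistic"] == pytest.approx(20.0)  # all E = 20

    def test_equal_rows_independent(self):
        res = association_test(np.array([[12, 30], [12, 30]]))
        assert res["statistic"] == pytest.approx(0.0)

    def test_zero_cells_use_haldane_correction(self):
        res = association_test(np.array([[40, 0], [0, 40]]))
        assert res["odds_ratio"] == pytest.approx((40.5 * 40.5) / (0.5 * 0.5))
        assert res["p_value"] < 0.05

    def test_zero_marginal_flagged(self):
        res = association_test(np.array([[0, 10], [0, 30]]))
        assert res["degenerate"] and np.isnan(res["p_value"])

    def test_association_recovery_short(self):
        """Coupled fate simulation is detected; odds ratio near generative 16."""
        rejections, ors = 0, []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            fates = simulate_loop_fates(1000, 0.5, 0.8, 0.2, rng)
            res = association_test(fate_table(fates["loop_fate"], fates["hm_fate"]))
            rejections += res["p_value"] < 0.05
            ors.append(res["odds_ratio"])
        assert rejections == 20
        assert 16 * 0.7 <= np.median(ors) <= 16 * 1.3


class TestNewLoops:
    CLASSES = {1: ONLY_H2AUB, 2: H2AUB_H3K27ME3, 3: ONLY_H2AUB}

    def test_fresh_anchor_detected(self):
        out = characterize_new_loops(loops_df([(1, 50)]), self.CLASSES, {1, 2, 7})
        assert out["new_nonbait_anchors"][ONLY_H2AUB] == [50]
        assert out["baitness_pct"]["Bait-Nonbait"] == 100.0

    def test_bait_bait_new_loop_adds_no_anchor(self):
        out = characterize_new_loops(loops_df([(1, 2)]), self.CLASSES, {1, 2})
        assert out["baitness_counts"] == {"Bait-Bait": 1}
        assert all(not v for v in out["new_nonbait_anchors"].values())

    def test_wt_anchor_not_counted_fresh(self):
        out = characterize_new_loops(loops_df([(2, 7)]), self.CLASSES, {1, 2, 7})
        assert all(not v for v in out["new_nonbait_anchors"].values())

    def test_venn_matches_brute_force(self, rng):
        bait_ids = set(range(0, 40))
        mk = lambda n: loops_df(
            sorted({(int(min(a, b)), int(max(a, b)))
                    for a, b in rng.integers(0, 60, size=(n, 2)) if a != b})
        )
        matched = {"disappeared": mk(30), "maintained": mk(30), "new": mk(30)}
        venn = anchor_venn(matched, bait_ids)
        sets = {
            k: (set(v["anchorA"]) | set(v["anchorB"])) & bait_ids
            for k, v in matched.items()
        }
        d, m, n = sets["disappeared"], sets["maintained"], sets["new"]
        assert venn["all_three"] == len(d & m & n)
        assert venn["disappeared_only"] == len(d - m - n)
        assert sum(venn.values()) == len(d | m | n)
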