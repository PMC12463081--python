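"""Bait typing, loop classification, hub detection and anchor annotation."""

import numpy as np
import pandas as pd
import pytest

from pcgloop.fragments import digest_genome
from pcgloop.intervals import GeneModel, GenomicInterval
from pcgloop.loops import (
    BAIT_BAIT,
    BAIT_NONBAIT,
    BOTH,
    FINAL_CLASSES,
    H2AUB_H3K27ME3,
    ONLY_H2AUB,
    PCGHUB_BOTH,
    PCGHUB_ONLY_H2AUB,
    PURE_H2AUB_H3K27ME3,
    PURE_ONLY_H2AUB,
    annotate_anchor_features,
    bait_anchor_venn,
    canonical_loops,
    classify_baitness,
    classify_loops,
    classify_pcg,
    detect_pcg_hub,
    gene_loop_span,
    loop_lengths,
    type_baits,
)


def loops_df(pairs, **extra):
    df = pd.DataFrame(pairs, columns=["anchorA", "anchorB"])
    df["score"] = 1.0
    for k, v in extra.items():
        df[k] = v
    return df


def brute_force_final_classes(pairs, bait_classes):
    """Independent oracle: materialize the Both-anchor seed set and test
    every loop against it by set intersection."""
    def pcg(a, b):
        ca, cb = bait_classes.get(a), bait_classes.get(b)
        present = {c for c in (ca, cb) if c}
        if present == {ONLY_H2AUB, H2AUB_H3K27ME3}:
            return BOTH
        if H2AUB_H3K27ME3 in present:
            return H2AUB_H3K27ME3
        return ONLY_H2AUB

    classes = [pcg(a, b) for a, b in pairs]
    seed = set()
    for (a, b), c in zip(pairs, classes):
        if c == BOTH:
            seed |= {a, b}
    out = []
    for (a, b), c in zip(pairs, classes):
        hub = c == BOTH or bool({a, b} & seed)
        if c == BOTH:
            out.append(PCGHUB_BOTH)
        elif c == ONLY_H2AUB:
            out.append(PCGHUB_ONLY_H2AUB if hub else PURE_ONLY_H2AUB)
        else:
            out.append("PcGhub_H2Aub_H3K27me3" if hub else PURE_H2AUB_H3K27ME3)
    return out


class TestTypeBaits:
    @pytest.fixture()
    def fm(self):
        # fragments [0,500), [500,1000) on chr1
        return digest_genome({"chr1": "A" * 496 + "GATC" + "A" * 500})

    def test_overlap_makes_comarked(self, fm):
        baits = type_baits([0], fm, [GenomicInterval("chr1", 400, 450)])
        assert baits.loc[0, "bait_class"] == H2AUB_H3K27ME3

    def test_half_open_non_overlap(self, fm):
        baits = type_baits([0], fm, [GenomicInterval("chr1", 500, 600)])
        assert baits.loc[0, "bait_class"] == ONLY_H2AUB

    def test_no_k27_peaks_all_only(self, fm):
        baits = type_baits([0, 1], fm, [])
        assert set(baits["bait_class"]) == {ONLY_H2AUB}


class TestBaitness:
    def test_partition_and_drop(self):
        classes = {1: ONLY_H2AUB, 2: H2AUB_H3K27ME3}
        loops = loops_df([(1, 2), (1, 7), (8, 9)])
        out, n_dropped = classify_baitness(loops, classes)
        assert n_dropped == 1
        assert list(out["baitness"]) == [BAIT_BAIT, BAIT_NONBAIT]
        # partition invariant
        assert (out["baitness"] == BAIT_BAIT).sum() + (
            out["baitness"] == BAIT_NONBAIT
        ).sum() == len(out)

    def test_canonical_anchor_order(self):
        out = canonical_loops(loops_df([(9, 3)]))
        assert (out.loc[0, "anchorA"], out.loc[0, "anchorB"]) == (3, 9)

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            canonical_loops(loops_df([(4, 4)]))


class TestPcgClassification:
    CLASSES = {1: ONLY_H2AUB, 2: H2AUB_H3K27ME3, 3: ONLY_H2AUB, 4: H2AUB_H3K27ME3}

    def classify(self, pairs, **kwargs):
        out, _ = classify_baitness(loops_df(pairs), self.CLASSES)
        return classify_pcg(out, self.CLASSES, **kwargs)

    def test_opposite_bait_classes_make_both(self):
        assert self.classify([(1, 2)])["pcg_class"].tolist() == [BOTH]

    def test_two_only_baits(self):
        assert self.classify([(1, 3)])["pcg_class"].tolist() == [ONLY_H2AUB]

    def test_comarked_bait_with_nonbait(self):
        assert self.classify([(2, 99)])["pcg_class"].tolist() == [H2AUB_H3K27ME3]

    def test_only_bait_with_nonbait(self):
        assert self.classify([(1, 99)])["pcg_class"].tolist() == [ONLY_H2AUB]

    def test_nonbait_k27_flag_opt_in(self):
        out = self.classify([(1, 99)], nonbait_k27={99})
        assert out["pcg_class"].tolist() == [H2AUB_H3K27ME3]
        assert out["nonbait_k27"].tolist() == [True]

    def test_three_way_partition(self):
        out = self.classify([(1, 2), (1, 3), (2, 4), (1, 99), (2, 99)])
        assert out["pcg_class"].isin([BOTH, ONLY_H2AUB, H2AUB_H3K27ME3]).all()


class TestHubDetection:
    CLASSES = {1: ONLY_H2AUB, 2: H2AUB_H3K27ME3, 3: ONLY_H2AUB, 5: ONLY_H2AUB,
               6: ONLY_H2AUB}

    def test_one_step_sharing(self):
        # L1=(1,2) Both; L2=(1,3) only-H2Aub shares anchor 1 -> hub
        out, _ = classify_loops(loops_df([(1, 2), (1, 3)]), self.CLASSES)
        assert out["final_class"].tolist() == [PCGHUB_BOTH, PCGHUB_ONLY_H2AUB]

    def test_independent_loop_is_pure(self):
        out, _ = classify_loops(loops_df([(1, 2), (5, 6)]), self.CLASSES)
        assert out.loc[1, "final_class"] == PURE_ONLY_H2AUB

    def test_no_both_loops_all_pure(self):
        out, _ = classify_loops(loops_df([(1, 3), (5, 6)]), self.CLASSES)
        assert not out["hub_member"].any()
        assert set(out["final_class"]) <= {PURE_ONLY_H2AUB, PURE_H2AUB_H3K27ME3}

    def test_one_step_not_transitive(self):
        # chain: Both(1,2) -- only(1,3) -- only(3,5)
        out, _ = classify_loops(loops_df([(1, 2), (1, 3), (3, 5)]), self.CLASSES)
        assert out.loc[1, "hub_member"]  # shares anchor 1 with the Both loop
        assert not out.loc[2, "hub_member"]  # one step only: 3,5 not in seed
        out_t, _ = classify_loops(
            loops_df([(1, 2), (1, 3), (3, 5)]), self.CLASSES, transitive=True
        )
        assert out_t["hub_member"].all()

    def test_monotone_in_both_loops(self, rng):
        """Adding a Both-loop never demotes a loop from hub to Pure."""
        classes = {i: (ONLY_H2AUB if i % 2 else H2AUB_H3K27ME3) for i in range(40)}
        pairs = [(int(a), int(b)) for a, b in rng.integers(0, 60, size=(80, 2)) if a != b]
        base, _ = classify_loops(loops_df(pairs), classes)
        grown, _ = classify_loops(loops_df(pairs + [(1, 2)]), classes)
        before = dict(zip(zip(base["anchorA"], base["anchorB"]), base["hub_member"]))
        after = dict(zip(zip(grown["anchorA"], grown["anchorB"]), grown["hub_member"]))
        for key, was_hub in before.items():
            if was_hub:
                assert after[key]

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(20):
            n_frag = int(rng.integers(20, 120))
            classes = {
                int(i): (ONLY_H2AUB if rng.random() < 0.6 else H2AUB_H3K27ME3)
                for i in rng.choice(n_frag, size=n_frag // 2, replace=False)
            }
            raw = rng.integers(0, n_frag, size=(int(rng.integers(10, 300)), 2))
            pairs = sorted(
                {(int(min(a, b)), int(max(a, b))) for a, b in raw if a != b
                 if a in classes or b in classes}
            )
            out, _ = classify_loops(loops_df(pairs), classes)
            expected = brute_force_final_classes(
                list(zip(out["anchorA"], out["anchorB"])), classes
            )
            assert out["final_class"].tolist() == expected
            # five-way partition
            assert out["final_class"].isin(FINAL_CLASSES).all()

    def test_venn_counts_match_brute_force(self, rng):
        classes = {int(i): ONLY_H2AUB for i in range(30)}
        raw = rng.integers(0, 60, size=(100, 2))
        pairs = sorted({(int(min(a, b)), int(max(a, b))) for a, b in raw if a != b})
        out, _ = classify_baitness(loops_df(pairs), classes)
        venn = bait_anchor_venn(out, classes)
        bb = out[out["baitness"] == BAIT_BAIT]
        bn = out[out["baitness"] == BAIT_NONBAIT]
        sbb = (set(bb["anchorA"]) | set(bb["anchorB"])) & set(classes)
        sbn = (set(bn["anchorA"]) | set(bn["anchorB"])) & set(classes)
        assert venn == {
            "bait_bait_only": len(sbb - sbn),
            "bait_nonbait_only": len(sbn - sbb),
            "shared": len(sbb & sbn),
        }


class TestGeometry:
    @pytest.fixture()
    def fm(self):
        # chr1 fragments [0,100), [100,200), [200,300); chr2 one fragment
        seq = "A" * 100 + "GATC" + "A" * 96 + "GATC" + "A" * 96
        return digest_genome({"chr1": seq, "chr2": "T" * 50})

    def test_midpoint_distance(self, fm):
        df = loops_df([(0, 2)])  # midpoints 50 and 250
        assert loop_lengths(df, fm).tolist() == [200.0]

    def test_adjacent_fragments(self, fm):
        assert loop_lengths(loops_df([(0, 1)]), fm).tolist() == [100.0]

    def test_trans_pair_flagged_nan(self, fm):
        assert np.isnan(loop_lengths(loops_df([(0, 3)]), fm)).all()

    def test_gene_loop_span_pairwise(self):
        # fragments of 100 bp; gene on fragment around 5000
        seq = "".join("A" * 96 + "GATC" for _ in range(100))
        fm = digest_genome({"chr1": seq})
        gene = GeneModel("g", GenomicInterval("chr1", 5000, 5080, "+"))
        on_gene = fm.containing("chr1", 5040)
        up1 = fm.containing("chr1", 1000)
        up2 = fm.containing("chr1", 3000)
        df = loops_df([(up1, on_gene), (up2, on_gene)])
        spans = gene_loop_span(df, gene, fm)
        assert spans == {"left-anchor": fm.midpoint(up2) - fm.midpoint(up1)}

    def test_gene_loop_span_needs_two_loops(self):
        seq = "".join("A" * 96 + "GATC" for _ in range(100))
        fm = digest_genome({"chr1": seq})
        gene = GeneModel("g", GenomicInterval("chr1", 5000, 5080, "+"))
        df = loops_df([(fm.containing("chr1", 1000), fm.containing("chr1", 5040))])
        assert gene_loop_span(df, gene, fm) is None

    def test_single_other_anchor_side_has_zero_span(self):
        seq = "".join("A" * 96 + "GATC" for _ in range(100))
        fm = digest_genome({"chr1": seq})
        gene = GeneModel("g", GenomicInterval("chr1", 5000, 5080, "+"))
        on_gene = fm.containing("chr1", 5040)
        df = loops_df([(fm.containing("chr1", 1000), on_gene),
                       (on_gene, fm.containing("chr1", 8000))])
        spans = gene_loop_span(df, gene, fm)
        assert spans["left-anchor"] == 0 and spans["right-anchor"] == 0


class TestAnchorAnnotation:
    @pytest.fixture()
    def fm(self):
        seq = "".join("A" * 196 + "GATC" for _ in range(50))
        return digest_genome({"chr1": seq})

    def test_precedence(self, fm):
        gene = GeneModel(
            "g",
            GenomicInterval("chr1", 2000, 3600, "+"),
            exons=(
                GenomicInterval("chr1", 2000, 2500, "+"),
                GenomicInterval("chr1", 3000, 3600, "+"),
            ),
        )
        inside_exon = fm.containing("chr1", 2100)
        exon_and_intron = fm.containing("chr1", 2450)  # fragment spans boundary
        intron_only = fm.containing("chr1", 2700)
        promoter = fm.containing("chr1", 1500)  # within [1000,2000) upstream window
        intergenic = fm.containing("chr1", 8000)
        labels = annotate_anchor_features(
            [inside_exon, exon_and_intron, intron_only, promoter, intergenic],
            fm,
            [gene],
        )
        assert labels.tolist() == ["exon", "exon", "intron", "promoter", "intergenic"]
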