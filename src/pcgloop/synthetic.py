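"""Seeded generator of toy capture Hi-C datasets with planted truth.

Emulates the statistical structure the pipeline is built to recover: a
small multi-chromosome genome whose GATC spacing follows a geometric gap
model, H2Aub peaks with a tunable H3K27me3 co-marking fraction, loop sets
with planted Both-loop-seeded hubs plus Pure loops and a Bait-Nonbait
fraction, a mutant genotype with coupled loop/histone-mark loss, and
expression depressed by co-marking and loop membership. Every planted
label is emitted in first-class truth tables; tests never re-derive truth
from the generated files. The generator is a pure function of
(config, seed): identical inputs give byte-identical outputs.

It does not simulate raw reads, ligation junctions or capture
hybridization efficiency.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .fragments import FragmentMap, digest_genome
from .intervals import GeneModel, GenomicInterval
from .loops import (
    BAIT_BAIT,
    BAIT_NONBAIT,
    BOTH,
    H2AUB_H3K27ME3,
    ONLY_H2AUB,
    PCGHUB_BOTH,
    PCGHUB_H2AUB_H3K27ME3,
    PCGHUB_ONLY_H2AUB,
    PURE_H2AUB_H3K27ME3,
    PURE_ONLY_H2AUB,
)
from .mutant import FATE_CELLS, H2AUB_MARK, HM_LOST, HM_MAINTAINED, K27_MARK, LOOP_LOST, LOOP_MAINTAINED
from .signal import SignalTrack

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class GenomeConfig:
    n_chroms: int = 2
    chrom_length: int = 400_000
    mean_fragment_gap: int = 260  # geometric GATC gap, ~genome-average DpnII spacing


@dataclass
class PeakConfig:
    n_h2aub: int = 400
    f_both: float = 0.4  # fraction of H2Aub peaks also H3K27me3-marked
    n_k27_only: int = 100
    peak_frac: float = 0.6  # peak width as a fraction of its fragment
    min_fragment_length: int = 150


@dataclass
class LoopConfig:
    n_both: int = 150
    n_hub_attached: int = 320
    n_pure_only: int = 30
    n_pure_k27: int = 20
    bait_nonbait_fraction: float = 0.32  # per hub-attached/Pure loop
    distance_median_bp: int = 25_000
    distance_sigma: float = 0.8  # log-normal shape


@dataclass
class MutantConfig:
    p_hm_loss: float = 0.5  # per bait fragment
    p_loss_given_hm_lost: float = 0.8
    p_loss_given_hm_kept: float = 0.2
    hm_log2fc: float = -1.0  # planted change at decreased fragments
    n_new: int = 100


@dataclass
class ExpressionConfig:
    baseline_log_mean: float = 2.0  # of ln(RPKM)
    baseline_log_sigma: float = 1.0
    m_k27: float = 0.5  # multiplier for H3K27me3-marked regions
    m_loop: float = 0.6  # multiplier for loop-anchor regions
    p_up: Mapping[str, float] = field(
        default_factory=lambda: {
            "Ll/Hl": 0.5, "Ll/Hm": 0.3, "Lm/Hl": 0.3, "Lm/Hm": 0.1,
        }
    )
    p_up_background: float = 0.05
    p_down: float = 0.05
    n_nonbait_genes: int = 200


@dataclass
class SimConfig:
    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    peaks: PeakConfig = field(default_factory=PeakConfig)
    loops: LoopConfig = field(default_factory=LoopConfig)
    mutant: MutantConfig = field(default_factory=MutantConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)

    def validate(self) -> None:
        for name, p in [
            ("f_both", self.peaks.f_both),
            ("bait_nonbait_fraction", self.loops.bait_nonbait_fraction),
            ("p_hm_loss", self.mutant.p_hm_loss),
            ("p_loss_given_hm_lost", self.mutant.p_loss_given_hm_lost),
            ("p_loss_given_hm_kept", self.mutant.p_loss_given_hm_kept),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        counts = [
            self.peaks.n_h2aub, self.peaks.n_k27_only, self.loops.n_both,
            self.loops.n_hub_attached, self.loops.n_pure_only,
            self.loops.n_pure_k27, self.mutant.n_new,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        kwargs = {}
        sections = {
            "genome": GenomeConfig, "peaks": PeakConfig, "loops": LoopConfig,
            "mutant": MutantConfig, "expression": ExpressionConfig,
        }
        for key, value in data.items():
            if key in sections:
                kwargs[key] = sections[key](**value)
            elif key == "seed":
                kwargs["seed"] = int(value)
            else:
                raise ValueError(f"unknown config section {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Genome


def _gatc_free(rng: np.random.Generator, length: int) -> str:
    """Random sequence of given length containing no GATC occurrence."""
    seq = "".join(BASES[rng.integers(0, 4, size=length)])
    while True:
        i = seq.find("GATC")
        if i < 0:
            return seq
        seq = seq[:i] + "T" + seq[i + 1 :]


def _simulate_chromosome(rng: np.random.Generator, length: int, mean_gap: int) -> str:
    parts = [_gatc_free(rng, int(rng.geometric(1.0 / mean_gap)))]
    total = len(parts[0])
    while total < length:
        gap = int(rng.geometric(1.0 / mean_gap))
        parts.append("GATC")
        parts.append(_gatc_free(rng, gap))
        total += 4 + gap
    return "".join(parts)[:length]


def simulate_genome(config: GenomeConfig, rng: np.random.Generator) -> dict[str, str]:
    return {
        f"chr{i + 1}": _simulate_chromosome(
            rng, config.chrom_length, config.mean_fragment_gap
        )
        for i in range(config.n_chroms)
    }


# ---------------------------------------------------------------------------
# Helpers


def _central_window(iv: GenomicInterval, frac: float) -> GenomicInterval:
    width = max(1, int(iv.length * frac))
    start = iv.start + (iv.length - width) // 2
    return GenomicInterval(iv.chrom, start, start + width)


class _Pool:
    """Per-chromosome fragment pool supporting nearest-to-position picks."""

    def __init__(self, fids: list[int], fragments: FragmentMap):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        grouped: dict[str, list[int]] = {}
        for fid in fids:
            grouped.setdefault(fragments.chrom_of(fid), []).append(fid)
        for chrom, ids in grouped.items():
            mids = np.array([fragments.midpoint(i) for i in ids])
            order = np.argsort(mids, kind="stable")
            self.by_chrom[chrom] = (
                np.array(ids)[order], mids[order]
            )

    @property
    def chroms(self) -> list[str]:
        return list(self.by_chrom)

    def size(self, chrom: str) -> int:
        return len(self.by_chrom.get(chrom, ((), ()))[0])

    def nearest(self, chrom: str, pos: int, exclude: int | None = None) -> int | None:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return None
        ids, mids = entry
        order = np.argsort(np.abs(mids - pos), kind="stable")
        for j in order[: min(len(order), 8)]:
            if exclude is None or int(ids[j]) != exclude:
                return int(ids[j])
        return None

    def random(self, chrom: str, rng: np.random.Generator,
               exclude: int | None = None) -> int | None:
        entry = self.by_chrom.get(chrom)
        if entry is None or len(entry[0]) == 0:
            return None
        for _ in range(20):
            fid = int(entry[0][rng.integers(len(entry[0]))])
            if exclude is None or fid != exclude:
                return fid
        return None


# ---------------------------------------------------------------------------
# Dataset container


@dataclass
class SimData:
    config: SimConfig
    genome: dict[str, str]
    fragments: FragmentMap
    h2aub_peaks: list[GenomicInterval]
    k27_peaks: list[GenomicInterval]
    loops_wt: pd.DataFrame  # loop_id, anchorA, anchorB, score
    loops_mut: pd.DataFrame
    tracks: dict[str, SignalTrack]  # h2aub_wt, h2aub_mut, k27_wt, k27_mut
    genes: list[GeneModel]
    expression: pd.DataFrame  # gene_id, expression
    de_labels: pd.DataFrame  # gene_id, de_label
    truth_loops: pd.DataFrame  # loop_id, baitness, pcg_class, final_class
    truth_fates: pd.DataFrame  # loop_id, loop_fate, hm_fate, cell
    truth_hm: pd.DataFrame  # fragment_id, mark, log2fc, decreased
    truth_gene_groups: pd.DataFrame  # gene_id, group

    def _loop_intervals(self, loops: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for r in loops.itertuples():
            ia = self.fragments.interval(r.anchorA)
            ib = self.fragments.interval(r.anchorB)
            rows.append(
                (ia.chrom, ia.start, ia.end, ib.chrom, ib.start, ib.end, r.score)
            )
        return pd.DataFrame(rows, columns=pio.LOOP_COLUMNS)

    def write(self, out_dir: str | Path) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}

        def save(key, fn, *args):
            paths[key] = str(out / fn)
            return paths[key]

        pio.write_fasta(self.genome, save("genome", "genome.fa"))
        pio.write_bed(self.h2aub_peaks, save("h2aub_peaks", "h2aub_peaks.bed"))
        pio.write_bed(self.k27_peaks, save("k27_peaks", "k27_peaks.bed"))
        pio.write_loop_table(
            self._loop_intervals(self.loops_wt), save("loops_wt", "loops_wt.tsv")
        )
        pio.write_loop_table(
            self._loop_intervals(self.loops_mut), save("loops_mut", "loops_mut.tsv")
        )
        for name, track in self.tracks.items():
            pio.write_bedgraph(track, save(name, f"{name}.bedGraph"))
        pio.write_gff3(self.genes, save("genes", "genes.gff3"))
        pio.write_table(self.expression, save("expression", "expression.tsv"))
        pio.write_table(self.de_labels, save("de_labels", "de_labels.tsv"))
        pio.write_table(self.truth_loops, save("truth_loops", "truth_loops.tsv"))
        pio.write_table(self.truth_fates, save("truth_fates", "truth_fates.tsv"))
        pio.write_table(self.truth_hm, save("truth_hm", "truth_hm.tsv"))
        pio.write_table(
            self.truth_gene_groups, save("truth_gene_groups", "truth_gene_groups.tsv")
        )
        return paths


# ---------------------------------------------------------------------------
# Generator


def generate(config: SimConfig, out_dir: str | Path | None = None) -> SimData:
    """Generate a full WT + mutant dataset with planted truth.

    Raises before any output is produced when the requested geometry is
    infeasible (e.g. more peaks than usable fragments).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pc, lc, mc, xc = config.peaks, config.loops, config.mutant, config.expression

    genome = simulate_genome(config.genome, rng)
    fragments = digest_genome(genome)

    eligible = [
        f.fragment_id
        for f in fragments.fragments
        if f.interval.length >= pc.min_fragment_length
    ]
    need = pc.n_h2aub + pc.n_k27_only
    if need > len(eligible):
        raise ValueError(
            f"infeasible geometry: {need} peak fragments requested but only "
            f"{len(eligible)} fragments of >= {pc.min_fragment_length} bp exist"
        )
    eligible = list(rng.permutation(eligible))

    # -- peaks and bait classes -------------------------------------------
    bait_fids = sorted(eligible[: pc.n_h2aub])
    k27_only_fids = sorted(eligible[pc.n_h2aub : pc.n_h2aub + pc.n_k27_only])
    nonbait_fids = eligible[pc.n_h2aub + pc.n_k27_only :]

    n_comarked = int(round(pc.f_both * pc.n_h2aub))
    comarked = set(
        int(i) for i in rng.choice(bait_fids, size=n_comarked, replace=False)
    ) if n_comarked else set()
    bait_class = {
        fid: (H2AUB_H3K27ME3 if fid in comarked else ONLY_H2AUB) for fid in bait_fids
    }

    h2aub_peaks = [
        _central_window(fragments.interval(fid), pc.peak_frac) for fid in bait_fids
    ]
    k27_peaks = [
        _central_window(fragments.interval(fid), pc.peak_frac * 0.8)
        for fid in sorted(comarked)
    ] + [
        _central_window(fragments.interval(fid), pc.peak_frac)
        for fid in k27_only_fids
    ]

    # -- anchor pools (disjoint hub vs pure) ------------------------------
    only_baits = [f for f in bait_fids if bait_class[f] == ONLY_H2AUB]
    k27_baits = [f for f in bait_fids if bait_class[f] == H2AUB_H3K27ME3]

    def reserve(pool: list[int], want_loops: int) -> tuple[list[int], list[int]]:
        if want_loops <= 0 or not pool:
            return [], pool
        k = min(len(pool) // 2, max(4, int(np.ceil(0.2 * len(pool)))))
        shuffled = list(rng.permutation(pool))
        return shuffled[:k], shuffled[k:]

    pure_only_pool, hub_only_pool = reserve(only_baits, lc.n_pure_only)
    pure_k27_pool, hub_k27_pool = reserve(k27_baits, lc.n_pure_k27)

    pool_hub_only = _Pool(hub_only_pool, fragments)
    pool_hub_k27 = _Pool(hub_k27_pool, fragments)
    pool_pure_only = _Pool(pure_only_pool, fragments)
    pool_pure_k27 = _Pool(pure_k27_pool, fragments)
    pool_nonbait = _Pool(list(map(int, nonbait_fids)), fragments)

    # -- WT loops ----------------------------------------------------------
    def draw_distance() -> int:
        return int(
            np.exp(rng.normal(np.log(lc.distance_median_bp), lc.distance_sigma))
        )

    pairs: set[tuple[int, int]] = set()
    loop_rows: list[tuple[int, int, str, str, str]] = []

    def add_loop(a: int, b: int, baitness: str, pcg: str, final: str) -> bool:
        key = (min(a, b), max(a, b))
        if a == b or key in pairs:
            return False
        pairs.add(key)
        loop_rows.append((*key, baitness, pcg, final))
        return True

    def target_pos(anchor: int, dist: int) -> int:
        sign = 1 if rng.random() < 0.5 else -1
        return fragments.midpoint(anchor) + sign * dist

    n_both_made = 0
    if k27_baits and only_baits:
        both_chroms = [
            c for c in pool_hub_only.chroms if pool_hub_k27.size(c) > 0
        ]
        attempts = 0
        while both_chroms and n_both_made < lc.n_both and attempts < 50 * max(1, lc.n_both):
            attempts += 1
            chrom = both_chroms[int(rng.integers(len(both_chroms)))]
            o = pool_hub_only.random(chrom, rng)
            k = pool_hub_k27.nearest(chrom, target_pos(o, draw_distance()))
            if k is None:
                k = pool_hub_k27.random(chrom, rng)
            if k is not None and add_loop(o, k, BAIT_BAIT, BOTH, PCGHUB_BOTH):
                n_both_made += 1

    seeds = sorted({a for row in loop_rows for a in row[:2]})
    seed_class = {s: bait_class[s] for s in seeds}

    # the Bait-Nonbait coin is drawn once per loop (not per placement
    # attempt), so the realized fraction stays binomial even when one
    # pair type rejects duplicates more often than the other
    n_hub_made = 0
    if seeds:
        for _ in range(lc.n_hub_attached):
            use_nonbait = rng.random() < lc.bait_nonbait_fraction
            for _attempt in range(50):
                s = seeds[int(rng.integers(len(seeds)))]
                chrom = fragments.chrom_of(s)
                cls = seed_class[s]
                pool = pool_nonbait if use_nonbait else (
                    pool_hub_only if cls == ONLY_H2AUB else pool_hub_k27
                )
                partner = pool.nearest(chrom, target_pos(s, draw_distance()), exclude=s)
                if partner is None:
                    partner = pool.random(chrom, rng, exclude=s)
                if partner is None:
                    continue
                final = (
                    PCGHUB_ONLY_H2AUB if cls == ONLY_H2AUB else PCGHUB_H2AUB_H3K27ME3
                )
                baitness = BAIT_NONBAIT if use_nonbait else BAIT_BAIT
                if add_loop(s, partner, baitness, cls, final):
                    n_hub_made += 1
                    break

    def make_pure(n: int, pool: _Pool, cls: str, final: str) -> int:
        made = 0
        chroms = pool.chroms
        if not chroms:
            return 0
        for _ in range(n):
            use_nonbait = rng.random() < lc.bait_nonbait_fraction
            for _attempt in range(50):
                chrom = chroms[int(rng.integers(len(chroms)))]
                a = pool.random(chrom, rng)
                if a is None:
                    continue
                partner_pool = (
                    pool_nonbait if use_nonbait or pool.size(chrom) < 2 else pool
                )
                partner = partner_pool.nearest(
                    chrom, target_pos(a, draw_distance()), exclude=a
                )
                if partner is None:
                    continue
                baitness = (
                    BAIT_NONBAIT
                    if partner_pool is pool_nonbait
                    else BAIT_BAIT
                )
                if add_loop(a, partner, baitness, cls, final):
                    made += 1
                    break
        return made

    # without realized Both-loops there is no hub: everything is Pure
    n_pure_only = lc.n_pure_only + (lc.n_hub_attached - n_hub_made if not seeds else 0)
    n_pure_k27 = lc.n_pure_k27 if k27_baits else 0
    n_pure_only += lc.n_pure_k27 if not k27_baits else 0
    make_pure(n_pure_only, pool_pure_only if pure_only_pool else _Pool(only_baits, fragments),
              ONLY_H2AUB, PURE_ONLY_H2AUB)
    make_pure(n_pure_k27, pool_pure_k27 if pure_k27_pool else _Pool(k27_baits, fragments),
              H2AUB_H3K27ME3, PURE_H2AUB_H3K27ME3)

    loop_ids = [f"loop{i:05d}" for i in range(len(loop_rows))]
    scores = np.round(rng.uniform(5.0, 15.0, size=len(loop_rows)), 3)
    loops_wt = pd.DataFrame(
        {
            "loop_id": loop_ids,
            "anchorA": [r[0] for r in loop_rows],
            "anchorB": [r[1] for r in loop_rows],
            "score": scores,
        }
    )
    truth_loops = pd.DataFrame(
        {
            "loop_id": loop_ids,
            "baitness": [r[2] for r in loop_rows],
            "pcg_class": [r[3] for r in loop_rows],
            "final_class": [r[4] for r in loop_rows],
        }
    )

    # -- mutant: fragment-level HM loss, then coupled loop loss -----------
    decreased = {
        fid: bool(rng.random() < mc.p_hm_loss) for fid in bait_fids
    }
    truth_hm_rows = []
    for fid in bait_fids:
        lfc = mc.hm_log2fc if decreased[fid] else 0.0
        truth_hm_rows.append((fid, H2AUB_MARK, lfc, decreased[fid]))
        if fid in comarked:
            truth_hm_rows.append((fid, K27_MARK, lfc, decreased[fid]))
    truth_hm = pd.DataFrame(
        truth_hm_rows, columns=["fragment_id", "mark", "log2fc", "decreased"]
    )

    hm_fate, loop_fate = [], []
    for r in loop_rows:
        bait_anchors = [a for a in r[:2] if a in bait_class]
        lost_hm = any(decreased[a] for a in bait_anchors)
        p_loss = mc.p_loss_given_hm_lost if lost_hm else mc.p_loss_given_hm_kept
        hm_fate.append(HM_LOST if lost_hm else HM_MAINTAINED)
        loop_fate.append(LOOP_LOST if rng.random() < p_loss else LOOP_MAINTAINED)
    truth_fates = pd.DataFrame(
        {
            "loop_id": loop_ids,
            "loop_fate": loop_fate,
            "hm_fate": hm_fate,
            "cell": [f"{l}/{h}" for l, h in zip(loop_fate, hm_fate)],
        }
    )

    maintained = loops_wt[[f == LOOP_MAINTAINED for f in loop_fate]]

    wt_anchor_ids = set(loops_wt["anchorA"]) | set(loops_wt["anchorB"])
    fresh_nonbait = [f for f in nonbait_fids if f not in wt_anchor_ids]
    pool_fresh = _Pool(list(map(int, fresh_nonbait)), fragments)
    mut_pairs = {
        (a, b) for a, b in zip(maintained["anchorA"], maintained["anchorB"])
    }
    pool_bait = _Pool(list(map(int, bait_fids)), fragments)
    new_rows = []
    attempts = 0
    while len(new_rows) < mc.n_new and attempts < 50 * max(1, mc.n_new):
        attempts += 1
        a = bait_fids[int(rng.integers(len(bait_fids)))]
        chrom = fragments.chrom_of(a)
        use_fresh = rng.random() < lc.bait_nonbait_fraction
        pool = pool_fresh if use_fresh else pool_bait
        partner = pool.nearest(chrom, target_pos(a, draw_distance()), exclude=a)
        if partner is None:
            continue
        key = (min(a, partner), max(a, partner))
        if key in pairs or key in mut_pairs or key[0] == key[1]:
            continue
        mut_pairs.add(key)
        new_rows.append(key)
    loops_mut = pd.concat(
        [
            maintained,
            pd.DataFrame(
                {
                    "loop_id": [f"newloop{i:05d}" for i in range(len(new_rows))],
                    "anchorA": [r[0] for r in new_rows],
                    "anchorB": [r[1] for r in new_rows],
                    "score": np.round(rng.uniform(5.0, 15.0, size=len(new_rows)), 3),
                }
            ),
        ],
        ignore_index=True,
    )

    # -- signal tracks -----------------------------------------------------
    def make_tracks(mark_fids: list[int], affected: set[int]) -> tuple[SignalTrack, SignalTrack]:
        wt_records, mut_records = [], []
        for fid in sorted(mark_fids):
            iv = fragments.interval(fid)
            value = float(np.exp(rng.normal(2.0, 0.4)))
            wt_records.append((iv, value))
            factor = 2.0 ** mc.hm_log2fc if fid in affected else 1.0
            mut_records.append((iv, value * factor))
        return SignalTrack(wt_records), SignalTrack(mut_records)

    dec_set = {f for f, d in decreased.items() if d}
    h2aub_wt, h2aub_mut = make_tracks(bait_fids, dec_set)
    k27_wt, k27_mut = make_tracks(
        sorted(comarked) + k27_only_fids, dec_set & comarked
    )
    tracks = {
        "h2aub_wt": h2aub_wt, "h2aub_mut": h2aub_mut,
        "k27_wt": k27_wt, "k27_mut": k27_mut,
    }

    # -- genes, expression, DE labels -------------------------------------
    n_nonbait_genes = min(xc.n_nonbait_genes, len(nonbait_fids))
    gene_frags = bait_fids + sorted(map(int, nonbait_fids[:n_nonbait_genes]))
    hub_anchor_set = {
        a for r in loop_rows if r[4].startswith("PcGhub") for a in r[:2]
    }
    pure_anchor_set = {
        a for r in loop_rows if r[4].startswith("Pure") for a in r[:2]
    }
    frag_cells: dict[int, list[str]] = {}
    for r, cell in zip(loop_rows, truth_fates["cell"]):
        for a in r[:2]:
            frag_cells.setdefault(a, []).append(cell)
    p_up_rank = {c: xc.p_up.get(c, 0.0) for c in FATE_CELLS}

    genes, expr_rows, de_rows, group_rows = [], [], [], []
    for i, fid in enumerate(gene_frags):
        iv = fragments.interval(fid)
        body = _central_window(iv, 0.6)
        strand = "+" if rng.random() < 0.5 else "-"
        body = GenomicInterval(body.chrom, body.start, body.end, strand)
        L = body.length
        if L >= 60:
            exons = (
                GenomicInterval(body.chrom, body.start, body.start + int(L * 0.4), strand),
                GenomicInterval(body.chrom, body.start + int(L * 0.6), body.end, strand),
            )
        else:
            exons = (body,)
        gene_id = f"gene{i:05d}"
        genes.append(GeneModel(gene_id, body, exons))

        expr = float(np.exp(rng.normal(xc.baseline_log_mean, xc.baseline_log_sigma)))
        if fid in comarked or fid in k27_only_fids:
            expr *= xc.m_k27
        if fid in wt_anchor_ids:
            expr *= xc.m_loop
        expr_rows.append((gene_id, round(expr, 4)))

        cells = frag_cells.get(fid)
        if cells:
            best = max(cells, key=lambda c: p_up_rank[c])
            p_up = p_up_rank[best]
        else:
            p_up = xc.p_up_background
        u = rng.random()
        label = "up" if u < p_up else ("down" if u < p_up + xc.p_down else "ns")
        de_rows.append((gene_id, label))

        if fid in bait_class:
            status = (
                "PcGhub" if fid in hub_anchor_set
                else "Pure" if fid in pure_anchor_set
                else "Nonloop"
            )
            group_rows.append((gene_id, f"{status}_{bait_class[fid]}"))

    sim = SimData(
        config=config,
        genome=genome,
        fragments=fragments,
        h2aub_peaks=h2aub_peaks,
        k27_peaks=k27_peaks,
        loops_wt=loops_wt,
        loops_mut=loops_mut,
        tracks=tracks,
        genes=genes,
        expression=pd.DataFrame(expr_rows, columns=["gene_id", "expression"]),
        de_labels=pd.DataFrame(de_rows, columns=["gene_id", "de_label"]),
        truth_loops=truth_loops,
        truth_fates=truth_fates,
        truth_hm=truth_hm,
        truth_gene_groups=pd.DataFrame(group_rows, columns=["gene_id", "group"]),
    )
    if out_dir is not None:
        sim.write(out_dir)
    return sim


# ---------------------------------------------------------------------------
# Truth comparison and tabular fate simulation


def planted_truth_compare(
    truth: pd.DataFrame,
    predicted: pd.DataFrame,
    on: str,
    truth_col: str,
    pred_col: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Confusion table and per-class precision/recall, truth vs pipeline.

    Identifiers must match exactly (one prediction per truth record);
    mismatches raise rather than silently dropping records.
    """
    t_ids, p_ids = set(truth[on]), set(predicted[on])
    if t_ids != p_ids:
        raise ValueError(
            f"identifier mismatch: {len(t_ids - p_ids)} truth-only, "
            f"{len(p_ids - t_ids)} prediction-only"
        )
    merged = truth[[on, truth_col]].merge(
        predicted[[on, pred_col]], on=on, suffixes=("_truth", "_pred")
    )
    tcol = truth_col if truth_col != pred_col else f"{truth_col}_truth"
    pcol = pred_col if truth_col != pred_col else f"{pred_col}_pred"
    confusion = pd.crosstab(merged[tcol], merged[pcol])
    classes = sorted(set(confusion.index) | set(confusion.columns))
    confusion = confusion.reindex(index=classes, columns=classes, fill_value=0)
    metrics = []
    for cls in classes:
        tp = confusion.loc[cls, cls]
        precision = tp / confusion[cls].sum() if confusion[cls].sum() else np.nan
        recall = tp / confusion.loc[cls].sum() if confusion.loc[cls].sum() else np.nan
        metrics.append((cls, precision, recall))
    return confusion, pd.DataFrame(metrics, columns=["class", "precision", "recall"])


def simulate_loop_fates(
    n_loops: int,
    p_hm_loss: float,
    p_loss_given_hm_lost: float,
    p_loss_given_hm_kept: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Loop-level fate table under the coupled loss model.

    Each loop independently loses its histone mark with ``p_hm_loss`` and
    then the loop itself with the conditional probability matching its HM
    fate. Used for association-recovery and type-I calibration studies
    where fragment-level structure is irrelevant.
    """
    hm_lost = rng.random(n_loops) < p_hm_loss
    p_loss = np.where(hm_lost, p_loss_given_hm_lost, p_loss_given_hm_kept)
    loop_lost = rng.random(n_loops) < p_loss
    return pd.DataFrame(
        {
            "hm_fate": np.where(hm_lost, HM_LOST, HM_MAINTAINED),
            "loop_fate": np.where(loop_lost, LOOP_LOST, LOOP_MAINTAINED),
        }
    )
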