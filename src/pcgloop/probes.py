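"""Length-conditional capture probe placement over enriched regions.

Hybridization probes of ~100 bp are placed at fixed fractional positions
of each peak, with the number of probes a step function of peak length:

* length < 300 bp  — one probe at the region center,
* 300 <= length <= 500 bp — two probes at one-third and two-thirds,
* length > 500 bp — three probes at one-quarter, one-half, three-quarters.

Fractional offsets are floored to integer base positions. A probe that
would overhang its source region is clipped to the region boundary and
flagged rather than discarded, so regions shorter than the probe length
still receive their probe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .intervals import GeneModel, GenomicInterval, IntervalSet, overlaps

DEFAULT_PROBE_LENGTH = 100


@dataclass(frozen=True)
class ProbeSite:
    source_region_id: str
    interval: GenomicInterval
    center: int
    clipped: bool = False


def _n_probes(length: int) -> int:
    if length < 300:
        return 1
    if length <= 500:
        return 2
    return 3


def probe_centers(region: GenomicInterval) -> list[int]:
    """Probe center offsets for a region, floored, strictly inside it."""
    L = region.length
    n = _n_probes(L)
    if n == 1:
        offsets = [L // 2]
    elif n == 2:
        offsets = [L // 3, 2 * L // 3]
    else:
        offsets = [L // 4, L // 2, 3 * L // 4]
    return [region.start + off for off in offsets]


def design_probes(
    region: GenomicInterval,
    probe_length: int = DEFAULT_PROBE_LENGTH,
    region_id: str = "region",
) -> list[ProbeSite]:
    """Place probe-binding sites in one region per the length rule.

    Each probe interval is ``[center - floor(p/2), center + ceil(p/2))``
    for probe length ``p``, clipped to the region if it would overhang
    (``clipped`` flag set). Deterministic.
    """
    if probe_length < 1:
        raise ValueError("probe_length must be >= 1")
    half_lo = probe_length // 2
    half_hi = probe_length - half_lo
    probes = []
    for i, center in enumerate(probe_centers(region)):
        start, end = center - half_lo, center + half_hi
        clipped = start < region.start or end > region.end
        if clipped:
            start = max(start, region.start)
            end = min(end, region.end)
        probes.append(
            ProbeSite(
                source_region_id=region_id,
                interval=GenomicInterval(region.chrom, start, end),
                center=center,
                clipped=clipped,
            )
        )
    return probes


def design_probes_for_regions(
    regions: Sequence[GenomicInterval],
    probe_length: int = DEFAULT_PROBE_LENGTH,
    region_ids: Sequence[str] | None = None,
) -> list[ProbeSite]:
    if region_ids is None:
        region_ids = [f"region{i}" for i in range(len(regions))]
    out: list[ProbeSite] = []
    for region, rid in zip(regions, region_ids):
        out.extend(design_probes(region, probe_length, rid))
    return out


def probe_sequences(probes: Iterable[ProbeSite], genome: dict[str, str]) -> dict[str, str]:
    """Extract genomic sequence under each probe (bait chemistry is metadata;
    downstream analysis consumes coordinates)."""
    seqs = {}
    for i, p in enumerate(probes):
        iv = p.interval
        seqs[f"{p.source_region_id}:{i}"] = genome[iv.chrom][iv.start : iv.end]
    return seqs


def probes_per_gene(
    probes: Iterable[ProbeSite], genes: Sequence[GeneModel]
) -> pd.Series:
    """Probe count per gene; a probe counts toward every gene whose body or
    promoter it overlaps (>= 1 bp). Genes with zero probes are included."""
    counts = pd.Series(0, index=[g.gene_id for g in genes], dtype=int, name="n_probes")
    footprint = IntervalSet()
    owner: dict[GenomicInterval, str] = {}
    for gene in genes:
        for iv in gene.body_and_promoter():
            footprint.add(iv)
            owner[iv] = gene.gene_id
    for probe in probes:
        hit_genes = {owner[iv] for iv in footprint.query(probe.interval)}
        for gid in hit_genes:
            counts[gid] += 1
    counts.index.name = "gene_id"
    return counts


def intersect_peak_replicates(
    replicates: Sequence[Sequence[GenomicInterval]],
) -> list[GenomicInterval]:
    """Conserved regions present in all replicate peak sets.

    Returns the base-level intersection across replicates, merged into
    maximal intervals — a utility for deriving the conserved peak set that
    seeds probe design when several biological replicates are available.
    """
    if not replicates:
        return []

    def merge(ivs: Sequence[GenomicInterval]) -> list[GenomicInterval]:
        out: list[GenomicInterval] = []
        for iv in sorted(ivs):
            if out and iv.chrom == out[-1].chrom and iv.start <= out[-1].end:
                prev = out.pop()
                out.append(GenomicInterval(prev.chrom, prev.start, max(prev.end, iv.end)))
            else:
                out.append(iv)
        return out

    current = merge(replicates[0])
    for rep in replicates[1:]:
        rep_merged = merge(rep)
        nxt: list[GenomicInterval] = []
        for a in current:
            for b in rep_merged:
                if overlaps(a, b):
                    nxt.append(
                        GenomicInterval(a.chrom, max(a.start, b.start), min(a.end, b.end))
                    )
        current = merge(nxt)
        if not current:
            break
    return current
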