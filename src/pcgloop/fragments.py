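"""In-silico restriction digestion and the genome-wide fragment map.

A restriction digest (DpnII, site GATC, for the capture Hi-C design this
package serves) partitions each chromosome into maximal fragments between
cut sites. Fragments are the atomic unit of the analysis: capture baits,
loop anchors and mutant-comparison bookkeeping are all expressed as
fragment ids. Cuts are placed immediately 5' of each site occurrence — a
blunt in-silico model; the enzyme's 5' overhang is irrelevant to fragment
bookkeeping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

DPNII_SITE = "GATC"


@dataclass(frozen=True)
class RestrictionFragment:
    """A maximal interval between in-silico cut sites."""

    fragment_id: int
    interval: GenomicInterval


def _cut_positions(seq: str, site: str) -> list[int]:
    """Start positions of every exact occurrence of ``site`` in ``seq``.

    Exact string match only: IUPAC ambiguity codes in the sequence never
    match the recognition site.
    """
    positions = []
    pos = seq.find(site)
    while pos != -1:
        positions.append(pos)
        pos = seq.find(site, pos + 1)
    return positions


class FragmentMap:
    """Genome-wide restriction-fragment map with fast region lookup.

    Fragments of one chromosome are non-overlapping, sorted and tile the
    chromosome exactly: concatenating them reconstructs ``[0, length)``.
    ``fragment_id`` is a stable integer index, unique genome-wide,
    increasing along each chromosome in input order.
    """

    def __init__(self, fragments: Sequence[RestrictionFragment],
                 chrom_lengths: Mapping[str, int]):
        self.fragments = list(fragments)
        self.chrom_lengths = dict(chrom_lengths)
        self._by_id = {f.fragment_id: f for f in self.fragments}
        if len(self._by_id) != len(self.fragments):
            raise ValueError("fragment_id values must be unique genome-wide")
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[RestrictionFragment]] = {}
        for f in self.fragments:
            by_chrom.setdefault(f.interval.chrom, []).append(f)
        for chrom, frs in by_chrom.items():
            frs.sort(key=lambda f: f.interval.start)
            starts = np.array([f.interval.start for f in frs], dtype=np.int64)
            ends = np.array([f.interval.end for f in frs], dtype=np.int64)
            ids = np.array([f.fragment_id for f in frs], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"fragments overlap on {chrom}")
            self._index[chrom] = (starts, ends, ids)
        self._validate_tiling()

    def _validate_tiling(self) -> None:
        for chrom, (starts, ends, _ids) in self._index.items():
            length = self.chrom_lengths.get(chrom)
            if length is None:
                raise ValueError(f"no chromosome length for {chrom}")
            ok = (
                starts[0] == 0
                and ends[-1] == length
                and np.array_equal(starts[1:], ends[:-1])
            )
            if not ok:
                raise ValueError(f"fragments do not tile chromosome {chrom}")

    # -- construction -----------------------------------------------------

    @classmethod
    def digest(cls, genome: Mapping[str, str], site: str = DPNII_SITE) -> "FragmentMap":
        """Digest a genome in silico.

        The cut is placed immediately 5' of each occurrence of ``site``;
        zero-length fragments (a site at position 0) are dropped.
        Deterministic. Empty chromosomes yield no fragments (warning).
        """
        if not site:
            raise ValueError("recognition site must be nonempty")
        site = site.upper()
        fragments: list[RestrictionFragment] = []
        chrom_lengths: dict[str, int] = {}
        next_id = 0
        for chrom, seq in genome.items():
            seq = seq.upper()
            if not seq:
                logger.warning("chromosome %s is empty; no fragments emitted", chrom)
                continue
            chrom_lengths[chrom] = len(seq)
            bounds = [0] + _cut_positions(seq, site) + [len(seq)]
            for start, end in zip(bounds, bounds[1:]):
                if end > start:  # drop empty fragments (site at position 0)
                    fragments.append(
                        RestrictionFragment(next_id, GenomicInterval(chrom, start, end))
                    )
                    next_id += 1
        return cls(fragments, chrom_lengths)

    # -- lookup ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.fragments)

    def fragment(self, fragment_id: int) -> RestrictionFragment:
        return self._by_id[fragment_id]

    def interval(self, fragment_id: int) -> GenomicInterval:
        return self._by_id[fragment_id].interval

    def midpoint(self, fragment_id: int) -> int:
        return self._by_id[fragment_id].interval.midpoint

    def chrom_of(self, fragment_id: int) -> str:
        return self._by_id[fragment_id].interval.chrom

    def fragments_on(self, chrom: str) -> list[RestrictionFragment]:
        if chrom not in self._index:
            return []
        _s, _e, ids = self._index[chrom]
        return [self._by_id[int(i)] for i in ids]

    def overlapping(self, region: GenomicInterval) -> list[int]:
        """Fragment ids overlapping ``region`` by >= 1 bp, sorted.

        Raises ``KeyError`` naming the chromosome when it is absent from
        the map — silent zero-hit answers would hide genome mismatches.
        """
        if region.chrom not in self._index:
            raise KeyError(
                f"chromosome {region.chrom!r} is not present in the fragment map"
            )
        starts, ends, ids = self._index[region.chrom]
        lo = int(np.searchsorted(ends, region.start, side="right"))
        hi = int(np.searchsorted(starts, region.end, side="left"))
        return [int(i) for i in ids[lo:hi]]

    def containing(self, chrom: str, pos: int) -> int:
        """Id of the fragment containing base ``pos``."""
        hits = self.overlapping(GenomicInterval(chrom, pos, pos + 1))
        if not hits:
            raise KeyError(f"no fragment contains {chrom}:{pos}")
        return hits[0]


def digest_genome(genome: Mapping[str, str], site: str = DPNII_SITE) -> FragmentMap:
    """Convenience alias for :meth:`FragmentMap.digest`."""
    return FragmentMap.digest(genome, site)


def map_regions_to_fragments(
    regions: Iterable[GenomicInterval], fragments: FragmentMap
) -> list[int]:
    """Every fragment id overlapping at least one region, sorted, deduplicated."""
    hit: set[int] = set()
    for region in regions:
        hit.update(fragments.overlapping(region))
    return sorted(hit)
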