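"""Genomic interval primitives.

All coordinates are 0-based, half-open ``[start, end)`` — the BED
convention — throughout the package. GFF3 input is converted on read.
Strand is ignored by every overlap query; it only matters for promoter
construction on :class:`GeneModel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from intervaltree import IntervalTree

VALID_STRANDS = frozenset({"+", "-", "."})


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a nonempty string")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared base pairs (0 if different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlaps(a: GenomicInterval, b: GenomicInterval, min_overlap: int = 1) -> bool:
    """True iff the two intervals share at least ``min_overlap`` bp.

    Strand-blind and symmetric. With the default ``min_overlap=1`` this is
    the usual half-open test: same chromosome and
    ``a.start < b.end and b.start < a.end``.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    return overlap_length(a, b) >= min_overlap


class IntervalSet:
    """An overlap-queryable collection of intervals (possibly overlapping).

    Thin per-chromosome wrapper around :class:`intervaltree.IntervalTree`.
    Used wherever an arbitrary region set (peaks, exons, promoters) must be
    intersected with queries; tiling structures (restriction-fragment maps,
    signal tracks) use sorted-array bisection instead.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def query(self, iv: GenomicInterval, min_overlap: int = 1) -> list[GenomicInterval]:
        """All stored intervals sharing >= min_overlap bp with ``iv``."""
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(iv.start, iv.end)]
        if min_overlap > 1:
            hits = [h for h in hits if overlap_length(h, iv) >= min_overlap]
        return sorted(hits)

    def overlaps_any(self, iv: GenomicInterval, min_overlap: int = 1) -> bool:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return False
        if min_overlap == 1:
            return tree.overlaps(iv.start, iv.end)
        return bool(self.query(iv, min_overlap))

    def __iter__(self) -> Iterator[GenomicInterval]:
        for tree in self._trees.values():
            for h in tree:
                yield h.data


@dataclass
class GeneModel:
    """A gene with exons and a strand-aware promoter window.

    The promoter is the ``promoter_window`` bp immediately upstream of the
    transcription start: left of the gene on ``+`` (clipped at 0), right of
    the gene on ``-``. Genes with strand ``.`` are treated as ``+``.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()
    promoter_window: int = 1000

    def __post_init__(self) -> None:
        self.exons = tuple(sorted(self.exons))
        for exon in self.exons:
            if exon.chrom != self.interval.chrom or not (
                self.interval.start <= exon.start and exon.end <= self.interval.end
            ):
                raise ValueError(
                    f"exon {exon} outside gene {self.gene_id} ({self.interval})"
                )

    @property
    def strand(self) -> str:
        return self.interval.strand

    def promoter(self) -> GenomicInterval | None:
        """Upstream promoter window; None when clipping leaves nothing."""
        if self.strand == "-":
            return GenomicInterval(
                self.interval.chrom,
                self.interval.end,
                self.interval.end + self.promoter_window,
                "-",
            )
        start = max(0, self.interval.start - self.promoter_window)
        if start >= self.interval.start:
            return None
        return GenomicInterval(
            self.interval.chrom, start, self.interval.start, self.interval.strand
        )

    def introns(self) -> tuple[GenomicInterval, ...]:
        """Gene-body gaps between consecutive exons."""
        out = []
        for left, right in zip(self.exons, self.exons[1:]):
            if left.end < right.start:
                out.append(
                    GenomicInterval(self.interval.chrom, left.end, right.start)
                )
        return tuple(out)

    def body_and_promoter(self) -> tuple[GenomicInterval, ...]:
        prom = self.promoter()
        return (self.interval,) if prom is None else (self.interval, prom)
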