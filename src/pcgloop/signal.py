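"""Coverage-density signal tracks (bedGraph-style).

A :class:`SignalTrack` holds, per chromosome, sorted non-overlapping
intervals with a nonnegative finite value each (e.g. ChIP-seq RPKM).
Bases not covered by any interval have signal 0.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator

import numpy as np

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)


class SignalTrack:
    def __init__(self, records: Iterable[tuple[GenomicInterval, float]] = ()) -> None:
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for iv, value in records:
            value = float(value)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"signal value must be finite and >= 0, got {value}")
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, value))
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                bad = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValueError(
                    f"overlapping signal intervals on {chrom} near "
                    f"{int(starts[bad + 1])}"
                )
            self._data[chrom] = (starts, ends, values)

    def __iter__(self) -> Iterator[tuple[GenomicInterval, float]]:
        for chrom in self._data:
            starts, ends, values = self._data[chrom]
            for s, e, v in zip(starts, ends, values):
                yield GenomicInterval(chrom, int(s), int(e)), float(v)

    def __len__(self) -> int:
        return sum(len(v[0]) for v in self._data.values())

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def genome_wide_mean(self) -> float:
        """Length-weighted mean value over all covered bases (0 if empty)."""
        total, mass = 0.0, 0.0
        for _chrom, (starts, ends, values) in self._data.items():
            lengths = (ends - starts).astype(float)
            total += float(np.sum(lengths * values))
            mass += float(np.sum(lengths))
        return total / mass if mass > 0 else 0.0

    def region_mean(self, region: GenomicInterval, mode: str = "full") -> float:
        """Length-weighted mean signal over ``region``.

        ``mode="full"`` divides by the full region length so uncovered
        bases contribute 0; ``mode="covered"`` divides by covered bases
        only (the bedmap ``--wmean`` dialect) and returns 0.0 for regions
        with no coverage. Regions on chromosomes absent from the track get
        0.0 with a warning.
        """
        if mode not in ("full", "covered"):
            raise ValueError(f"unknown mode {mode!r}")
        data = self._data.get(region.chrom)
        if data is None:
            logger.warning(
                "chromosome %s absent from signal track; occupancy 0", region.chrom
            )
            return 0.0
        starts, ends, values = data
        lo = int(np.searchsorted(ends, region.start, side="right"))
        hi = int(np.searchsorted(starts, region.end, side="left"))
        if lo >= hi:
            return 0.0
        ov = (
            np.minimum(ends[lo:hi], region.end) - np.maximum(starts[lo:hi], region.start)
        ).astype(float)
        weighted = float(np.sum(ov * values[lo:hi]))
        denom = float(region.length) if mode == "full" else float(np.sum(ov))
        return weighted / denom if denom > 0 else 0.0
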