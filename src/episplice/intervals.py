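"""Genomic interval primitives shared across the pipeline.

All coordinates are 0-based half-open internally ([start, end)).  GFF3 input
(1-based closed) and rMATS/MANorm dialects are converted on load; BED-style
I/O passes through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterable, Iterator

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def intersection_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance_to_point(self, chrom: str, pos: int) -> float:
        """Minimum distance from any base of the interval to a point.

        0 when the point lies inside the interval; ``inf`` across chromosomes.
        """
        if chrom != self.chrom:
            return float("inf")
        if self.start <= pos < self.end:
            return 0.0
        if pos < self.start:
            return float(self.start - pos)
        return float(pos - (self.end - 1))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


class IntervalIndex:
    """Per-chromosome interval tree over (interval, payload) pairs.

    Thin wrapper around :mod:`intervaltree` that keeps the pipeline's
    half-open convention explicit and returns payloads rather than tree nodes.
    """

    def __init__(self, items: Iterable[tuple[GenomicInterval, Any]] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for interval, payload in items:
            self.add(interval, payload)

    def add(self, interval: GenomicInterval, payload: Any) -> None:
        tree = self._trees.setdefault(interval.chrom, IntervalTree())
        tree.addi(interval.start, interval.end, payload)

    def query(self, chrom: str, start: int, end: int) -> list[Any]:
        """Payloads of all intervals intersecting [start, end) on chrom."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(start, end)]

    def query_interval(self, interval: GenomicInterval) -> list[Any]:
        return self.query(interval.chrom, interval.start, interval.end)

    def __iter__(self) -> Iterator[Any]:
        for tree in self._trees.values():
            for hit in tree:
                yield hit.data
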