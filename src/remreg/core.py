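"""Genome coordinate model and interval algebra.

Internally every span is 0-based half-open ``[start, end)`` (the BED
convention). Coordinates printed in genome browsers and in reports are
1-based inclusive; :meth:`GenomicInterval.from_printed` /
:meth:`GenomicInterval.to_printed` bridge the two. Strand is carried for
interoperability but ignored by every operation in this package: the
prediction procedure is strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Strand",
    "CoordinateError",
    "intersect_all",
]


class CoordinateError(ValueError):
    """Raised for invalid genomic coordinates (inverted, non-positive, ...)."""


class Strand(Enum):
    FORWARD = "+"
    REVERSE = "-"
    UNSTRANDED = "."


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name (non-empty).
    start : int
        0-based inclusive start, ``>= 0``.
    end : int
        0-based exclusive end, ``> start``.
    """

    chrom: str
    start: int
    end: int
    strand: Strand = field(default=Strand.UNSTRANDED, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise CoordinateError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid span [{self.start}, {self.end}): require 0 <= start < end"
            )

    @classmethod
    def from_printed(cls, start_1based: int, end_1based: int, chrom: str,
                     strand: Strand = Strand.UNSTRANDED) -> "GenomicInterval":
        """Build an interval from 1-based inclusive (browser-style) coordinates."""
        if start_1based < 1:
            raise CoordinateError(f"1-based start must be >= 1, got {start_1based}")
        if end_1based < start_1based:
            raise CoordinateError(
                f"inverted span: start {start_1based} > end {end_1based}"
            )
        return cls(chrom, start_1based - 1, end_1based, strand)

    def to_printed(self) -> tuple[int, int]:
        """Return the 1-based inclusive ``(start, end)`` pair for reports."""
        return self.start + 1, self.end

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two half-open spans share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_position(self, pos_1based: int) -> bool:
        """Containment of a 1-based single-base position."""
        return self.start < pos_1based <= self.end

    def gap_to(self, other: "GenomicInterval") -> int:
        """Distance in bp between nearest edges; 0 if overlapping or abutting."""
        if self.chrom != other.chrom:
            raise CoordinateError(
                f"intervals on different chromosomes: {self.chrom} vs {other.chrom}"
            )
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end

    def __str__(self) -> str:  # browser-style, for logs and reports
        s, e = self.to_printed()
        return f"{self.chrom}:{s:,}-{e:,}"


def _interval_of(obj) -> GenomicInterval:
    """Accept either a bare interval or any object with an ``interval`` field."""
    return obj if isinstance(obj, GenomicInterval) else obj.interval


def intersect_all(query: GenomicInterval, features: Sequence) -> list:
    """Return the features overlapping *query*, preserving input order.

    *features* may be ``GenomicInterval`` objects or anything carrying an
    ``interval`` attribute (e.g. scored features). Input may be unsorted.
    Equivalent to a pairwise overlap scan.
    """
    tree = IntervalTree()
    for idx, feat in enumerate(features):
        iv = _interval_of(feat)
        if iv.chrom == query.chrom:
            tree.addi(iv.start, iv.end, idx)
    hits = sorted(node.data for node in tree.overlap(query.start, query.end))
    return [features[i] for i in hits]


def span_of(intervals: Iterable[GenomicInterval]) -> GenomicInterval:
    """Smallest interval covering all inputs; inputs must share a chromosome."""
    ivs = list(intervals)
    if not ivs:
        raise CoordinateError("cannot take the span of zero intervals")
    chroms = {iv.chrom for iv in ivs}
    if len(chroms) != 1:
        raise CoordinateError(f"intervals span multiple chromosomes: {sorted(chroms)}")
    return GenomicInterval(ivs[0].chrom, min(iv.start for iv in ivs), max(iv.end for iv in ivs))
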