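"""Hi-C contact-map binning and interaction ranking (procedure Steps 1-3).

The genome is partitioned into fixed-size bins (typically 1 Mb for a first
pass, 100 kb for refinement). A gene is located to the bin(s) it intersects,
and every other bin on the chromosome is ranked by its total raw contact
count with the gene bins. Raw counts are used throughout — no ICE/matrix
balancing — because the ranking only needs the within-row ordering and the
source data are pre-binned raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import CoordinateError, GenomicInterval

__all__ = ["ContactMap", "InteractionRanking", "bin_of", "gene_bins",
           "rank_interacting", "interaction_summary"]


def bin_of(pos_1based: int, bin_size: int) -> int:
    """0-based start of the bin containing a 1-based genomic position."""
    if pos_1based < 1:
        raise CoordinateError(f"position must be >= 1, got {pos_1based}")
    if bin_size <= 0:
        raise CoordinateError(f"bin size must be positive, got {bin_size}")
    return (pos_1based - 1) // bin_size * bin_size


def gene_bins(gene: GenomicInterval, bin_size: int) -> list[int]:
    """Ascending 0-based starts of every bin intersecting the gene span."""
    if bin_size <= 0:
        raise CoordinateError(f"bin size must be positive, got {bin_size}")
    first = gene.start // bin_size * bin_size
    last = (gene.end - 1) // bin_size * bin_size
    return list(range(first, last + bin_size, bin_size))


@dataclass
class ContactMap:
    """Sparse symmetric intra-chromosomal contact counts at a fixed bin size."""

    chrom: str
    bin_size: int
    counts: dict[tuple[int, int], int] = field(default_factory=dict)

    def _key(self, i: int, j: int) -> tuple[int, int]:
        for b in (i, j):
            if b % self.bin_size != 0 or b < 0:
                raise CoordinateError(
                    f"bin start {b} is not a non-negative multiple of {self.bin_size}")
        return (i, j) if i <= j else (j, i)

    def set_count(self, i: int, j: int, count: int) -> None:
        if count < 0:
            raise ValueError(f"negative contact count {count}")
        self.counts[self._key(i, j)] = count

    def count(self, i: int, j: int) -> int:
        return self.counts.get(self._key(i, j), 0)

    def bins(self) -> list[int]:
        """Ascending starts of every bin mentioned in the map."""
        seen = {b for key in self.counts for b in key}
        return sorted(seen)

    def bin_interval(self, bin_start: int) -> GenomicInterval:
        return GenomicInterval(self.chrom, bin_start, bin_start + self.bin_size)

    def total_with(self, bins: list[int], other: int) -> int:
        """Total contact count between *other* and the given bin set."""
        return sum(self.count(g, other) for g in bins)


@dataclass
class InteractionRanking:
    """Bins ranked by total contact count with the gene-containing bin(s).

    ``ranked`` is sorted by descending count, ties broken by ascending bin
    start; every listed count is >= ``min_count``. When the self bins are
    excluded from the ranking their totals are kept in ``self_counts``.
    """

    gene_bins: list[int]
    ranked: list[tuple[int, int]]
    min_count: int
    self_counts: dict[int, int] = field(default_factory=dict)


def _check_gene_bins(cmap: ContactMap, bins: list[int]) -> None:
    if not bins:
        raise ValueError("gene_bins must be non-empty")
    for b in bins:
        if b % cmap.bin_size != 0 or b < 0:
            raise CoordinateError(
                f"gene bin {b} is not a non-negative multiple of bin size {cmap.bin_size}")


def rank_interacting(cmap: ContactMap, gene_bin_starts: list[int],
                     min_count: int = 0, include_self: bool = True) -> InteractionRanking:
    """Rank every bin in the map by its total contact count with the gene bins.

    Each bin's total is the sum of its counts against every gene bin (for a
    single-bin gene this is just the row of the contact matrix). Bins whose
    total falls below *min_count* are dropped, as are zero-total bins (an
    all-zero map ranks nothing). With ``include_self=False`` the gene bins
    are removed from the ranking and reported separately.
    """
    _check_gene_bins(cmap, gene_bin_starts)
    if min_count < 0:
        raise ValueError(f"min_count must be >= 0, got {min_count}")
    gene_set = set(gene_bin_starts)
    totals = {b: cmap.total_with(gene_bin_starts, b)
              for b in set(cmap.bins()) | gene_set}
    self_counts = {b: totals[b] for b in sorted(gene_set)}
    candidates = totals if include_self else {
        b: c for b, c in totals.items() if b not in gene_set}
    ranked = sorted(((b, c) for b, c in candidates.items() if c >= min_count and c > 0),
                    key=lambda bc: (-bc[1], bc[0]))
    return InteractionRanking(sorted(gene_set), ranked, min_count,
                              {} if include_self else self_counts)


def interaction_summary(cmap: ContactMap, gene_bin_starts: list[int],
                        include_zero: bool = False) -> pd.DataFrame:
    """Exhaustive per-bin contact totals with the gene bins, for reporting.

    Returns a DataFrame with columns ``bin_start`` and ``total_count`` in
    ascending bin order; zero-count bins are included on request.
    """
    if not gene_bin_starts:
        return pd.DataFrame(columns=["bin_start", "total_count"])
    _check_gene_bins(cmap, gene_bin_starts)
    rows = [(b, cmap.total_with(gene_bin_starts, b)) for b in cmap.bins()]
    if not include_zero:
        rows = [r for r in rows if r[1] > 0]
    return pd.DataFrame(rows, columns=["bin_start", "total_count"])
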