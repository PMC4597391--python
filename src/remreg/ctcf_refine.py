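"""CTCF-boundary refinement of interacting fragments (procedure Step 4).

The binned interacting fragments are narrowed to a search region delimited
by CTCF-binding sites flanking the gene: the DNA between an upstream CTCF
site and the gene, and between the gene and a downstream CTCF site, is where
remotely acting regulatory elements are sought. CTCF sites within 5 kb of
each other are merged into a single boundary cluster, and sites inside the
gene body are ignored. Two boundary policies are offered:

* ``outermost`` (default) — the farthest CTCF cluster from the gene within
  the union of interacting bins bounds the region on each side, whether weak
  or strong (weak boundaries are flagged). This is the permissive reading
  that maximises the searched area.
* ``strict`` — the strong CTCF cluster nearest the gene bounds each side;
  weak sites cannot act as boundaries.

When a side has no admissible CTCF site the region falls back to the edge of
the interacting-bin union on that side, recorded as a sentinel boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from .core import CoordinateError, GenomicInterval, span_of
from .io_formats import ScoredFeature

__all__ = ["CtcfSite", "CtcfCluster", "Boundary", "SearchRegion",
           "classify_ctcf", "cluster_sites", "refine_search_region"]

DEFAULT_STRENGTH_THRESHOLD = 500  # weak < 500 <= strong, on the 0-1000 scale
DEFAULT_MERGE_GAP = 5_000  # bp; sites closer than this form one boundary cluster


@dataclass(frozen=True)
class CtcfSite:
    interval: GenomicInterval
    score: int
    strength: Literal["weak", "strong"]
    cell_line: str = ""


def classify_ctcf(site: ScoredFeature, threshold: int = DEFAULT_STRENGTH_THRESHOLD) -> CtcfSite:
    """Label a scored CTCF site weak or strong: strong iff score >= threshold."""
    strength = "strong" if site.score >= threshold else "weak"
    return CtcfSite(site.interval, site.score, strength, site.cell_line)


@dataclass(frozen=True)
class CtcfCluster:
    """One or more CTCF sites merged into a single putative boundary."""

    interval: GenomicInterval  # span of the member sites
    sites: tuple[CtcfSite, ...]

    @property
    def strength(self) -> str:
        return "strong" if any(s.strength == "strong" for s in self.sites) else "weak"

    @property
    def max_score(self) -> int:
        return max(s.score for s in self.sites)


def cluster_sites(sites: Sequence[CtcfSite], merge_gap: int = DEFAULT_MERGE_GAP) -> list[CtcfCluster]:
    """Merge CTCF sites whose gaps are <= merge_gap into boundary clusters."""
    ordered = sorted(sites, key=lambda s: (s.interval.start, s.interval.end))
    clusters: list[list[CtcfSite]] = []
    for site in ordered:
        if clusters and site.interval.start - max(s.interval.end for s in clusters[-1]) <= merge_gap:
            clusters[-1].append(site)
        else:
            clusters.append([site])
    return [CtcfCluster(span_of([s.interval for s in grp]), tuple(grp)) for grp in clusters]


@dataclass(frozen=True)
class Boundary:
    """One side of a search region: a CTCF cluster, or the fragment edge."""

    kind: Literal["ctcf", "fragment_edge"]
    position: int  # 0-based boundary coordinate
    cluster: CtcfCluster | None = None

    @property
    def strength(self) -> str | None:
        return self.cluster.strength if self.cluster else None

    def describe(self) -> str:
        if self.kind == "fragment_edge":
            return f"interacting-fragment edge at {self.position:,}"
        return (f"{self.strength} CTCF boundary {self.cluster.interval} "
                f"(max score {self.cluster.max_score}/1000)")


@dataclass
class SearchRegion:
    """The CTCF-bounded region searched for regulatory elements."""

    interval: GenomicInterval
    upstream_boundary: Boundary
    downstream_boundary: Boundary
    rationale: str = ""

    def to_dict(self) -> dict:
        s, e = self.interval.to_printed()
        return {
            "chrom": self.interval.chrom,
            "start_1based": s,
            "end_1based": e,
            "upstream_boundary": self.upstream_boundary.describe(),
            "downstream_boundary": self.downstream_boundary.describe(),
            "rationale": self.rationale,
        }


def refine_search_region(
    gene: GenomicInterval,
    interacting_bins: Sequence[GenomicInterval],
    ctcf_sites: Sequence[CtcfSite],
    policy: Literal["outermost", "strict"] = "outermost",
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> SearchRegion:
    """Derive the CTCF-bounded search region around a gene.

    Parameters
    ----------
    gene : GenomicInterval
        The gene whose remote regulatory elements are sought.
    interacting_bins : sequence of GenomicInterval
        Bins selected by the interaction ranking (Step 3); the search region
        never extends past their union.
    ctcf_sites : sequence of CtcfSite
        Classified CTCF sites (any order; order does not affect the result).
    policy : {"outermost", "strict"}
        Boundary selection policy (see module docstring).
    """
    if not interacting_bins:
        raise ValueError("no interacting bins: Step 3 must select at least one bin")
    if any(b.chrom != gene.chrom for b in interacting_bins):
        raise CoordinateError("interacting bins must lie on the gene's chromosome")
    span = span_of(list(interacting_bins))

    admissible = [
        s for s in ctcf_sites
        if s.interval.chrom == gene.chrom
        and any(s.interval.overlaps(b) for b in interacting_bins)
        and not s.interval.overlaps(gene)  # sites inside the gene body are ignored
    ]
    upstream = cluster_sites([s for s in admissible if s.interval.end <= gene.start], merge_gap)
    downstream = cluster_sites([s for s in admissible if s.interval.start >= gene.end], merge_gap)

    def pick(clusters: list[CtcfCluster], side: str) -> Boundary:
        pool = clusters if policy == "outermost" else [
            c for c in clusters if c.strength == "strong"]
        if not pool:
            edge = span.start if side == "up" else span.end
            return Boundary("fragment_edge", edge)
        if side == "up":
            best = (min if policy == "outermost" else max)(pool, key=lambda c: c.interval.start)
            return Boundary("ctcf", max(best.interval.start, span.start), best)
        best = (max if policy == "outermost" else min)(pool, key=lambda c: c.interval.end)
        return Boundary("ctcf", min(best.interval.end, span.end), best)

    up = pick(upstream, "up")
    down = pick(downstream, "down")
    region = GenomicInterval(gene.chrom, up.position, down.position)
    rationale = (f"policy={policy}; upstream: {up.describe()}; "
                 f"downstream: {down.describe()}")
    return SearchRegion(region, up, down, rationale)
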