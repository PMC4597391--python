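"""Epigenetic evidence integration (procedure Step 5).

Candidate regulatory regions inside the CTCF-bounded search region are
anchored on open-chromatin/occupancy evidence: clusters of TFBS and DNaseI
hypersensitive features whose mutual gaps are at most ``cluster_gap``.
A cluster becomes a candidate when it is corroborated by at least
``min_mark_classes`` distinct mark classes among H3K4me1, H3K27ac, H3K4me3,
enhancer calls and active ChromHMM states. The candidate interval is the
anchor-cluster span itself — not widened to the (much broader) mark domains,
since the biochemical mark assays capture extended regions whose boundaries
are imprecise.

"Enrichment" here means presence/overlap of pre-called enriched regions, not
a statistical test: the inputs are already peak/region calls.

Cell-line handling mirrors common ENCODE practice when one karyotypically
normal line anchors the analysis: features from the configured primary cell
line are preferred, and features from other lines are consulted only for
mark classes absent from the primary line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .core import CoordinateError, GenomicInterval, intersect_all, span_of
from .ctcf_refine import SearchRegion
from .io_formats import FeatureTrack, ScoredFeature, TrackClass

__all__ = ["RegionClass", "CandidateRegion", "EvidenceConfig",
           "find_candidates", "classify_candidate", "distance_to_gene"]

ANCHOR_CLASSES = (TrackClass.TFBS, TrackClass.DNASE)
MARK_CLASSES = (TrackClass.H3K4ME1, TrackClass.H3K27AC, TrackClass.H3K4ME3,
                TrackClass.ENHANCER, TrackClass.CHROMHMM)


class RegionClass(Enum):
    PROMOTER_LIKE = "promoter_like"
    ENHANCER_LIKE = "enhancer_like"
    UNCLASSIFIED = "unclassified"


@dataclass
class EvidenceConfig:
    """Tunables for candidate detection.

    cluster_gap : bp
        Maximum gap between anchor features (TFBS/DNase) in one cluster.
    min_mark_classes : int
        Minimum number of distinct corroborating mark classes.
    primary_cell_line : str
        Preferred cell line; other lines fill in absent mark classes only.
    """

    cluster_gap: int = 200
    min_mark_classes: int = 1
    primary_cell_line: str = ""


@dataclass
class CandidateRegion:
    """A predicted regulatory region with its supporting evidence."""

    interval: GenomicInterval
    region_class: RegionClass = RegionClass.UNCLASSIFIED
    evidence: list[tuple[TrackClass, ScoredFeature]] = field(default_factory=list)
    distance_to_gene: int | None = None  # signed bp; negative = upstream
    search_region: SearchRegion | None = None

    def evidence_classes(self) -> set[TrackClass]:
        return {cls for cls, _ in self.evidence}

    def features_of(self, cls: TrackClass) -> list[ScoredFeature]:
        return [f for c, f in self.evidence if c is cls]

    def to_dict(self) -> dict:
        s, e = self.interval.to_printed()
        out = {
            "chrom": self.interval.chrom,
            "start_1based": s,
            "end_1based": e,
            "class": self.region_class.value,
            "evidence": [
                {"track_class": cls.value, "name": f.name, "score": f.score,
                 "cell_line": f.cell_line,
                 "start_1based": f.interval.to_printed()[0],
                 "end_1based": f.interval.to_printed()[1]}
                for cls, f in self.evidence
            ],
        }
        if self.distance_to_gene is not None:
            out["distance_to_gene_bp"] = self.distance_to_gene
            out["distance_to_gene_kb"] = round(self.distance_to_gene / 1000, 1)
        return out


def _is_active_chromhmm(feature: ScoredFeature) -> bool:
    return "active" in feature.name.lower()


def _select_by_cell_line(tracks: Sequence[FeatureTrack], primary: str) -> dict[TrackClass, list[ScoredFeature]]:
    """Pool features per class, applying the primary-cell-line preference."""
    pooled: dict[TrackClass, list[ScoredFeature]] = {}
    for track in tracks:
        pooled.setdefault(track.track_class, []).extend(track.features)
    if not primary:
        return pooled
    selected = {}
    for cls, feats in pooled.items():
        in_primary = [f for f in feats if f.cell_line == primary]
        selected[cls] = in_primary if in_primary else feats
    return selected


def _cluster_anchors(anchors: list[ScoredFeature], gap: int) -> list[list[ScoredFeature]]:
    ordered = sorted(anchors, key=lambda f: (f.interval.start, f.interval.end))
    clusters: list[list[ScoredFeature]] = []
    right = None
    for feat in ordered:
        if clusters and feat.interval.start - right <= gap:
            clusters[-1].append(feat)
            right = max(right, feat.interval.end)
        else:
            clusters.append([feat])
            right = feat.interval.end
    return clusters


def find_candidates(
    search_region: SearchRegion,
    tracks: Sequence[FeatureTrack],
    config: EvidenceConfig | None = None,
    gene: GenomicInterval | None = None,
) -> list[CandidateRegion]:
    """Emit candidate regulatory regions within the search region.

    Requires at least one anchor track (TFBS or DNase). Candidates are
    returned sorted by ascending start; the result is invariant under
    permutation of the input tracks and of features within tracks.
    """
    config = config or EvidenceConfig()
    if not tracks:
        raise ValueError("no feature tracks supplied")
    region = search_region.interval
    for track in tracks:
        wrong = [f for f in track.features if f.interval.chrom != region.chrom]
        if wrong:
            raise CoordinateError(
                f"{track.track_class.value} track has features on "
                f"{wrong[0].interval.chrom}, expected {region.chrom}")
    if not any(t.track_class in ANCHOR_CLASSES for t in tracks):
        raise ValueError("need at least one TFBS or DNase track to anchor candidates")

    pooled = _select_by_cell_line(tracks, config.primary_cell_line)
    anchors = [f for cls in ANCHOR_CLASSES for f in pooled.get(cls, [])
               if f.interval.overlaps(region)]
    anchor_class_of = {id(f): cls for cls in ANCHOR_CLASSES for f in pooled.get(cls, [])}

    candidates = []
    for cluster in _cluster_anchors(anchors, config.cluster_gap):
        raw_span = span_of([f.interval for f in cluster])
        span = GenomicInterval(region.chrom,
                               max(raw_span.start, region.start),
                               min(raw_span.end, region.end))
        evidence: list[tuple[TrackClass, ScoredFeature]] = [
            (anchor_class_of[id(f)], f) for f in cluster]
        mark_classes_found = set()
        for cls in MARK_CLASSES:
            for feat in intersect_all(span, pooled.get(cls, [])):
                if cls is TrackClass.CHROMHMM and not _is_active_chromhmm(feat):
                    continue
                evidence.append((cls, feat))
                mark_classes_found.add(cls)
        if len(mark_classes_found) < config.min_mark_classes:
            continue
        evidence.sort(key=lambda e: (e[0].value, e[1].interval.start, e[1].name))
        cand = CandidateRegion(span, evidence=evidence, search_region=search_region)
        cand.region_class = classify_candidate(cand)
        if gene is not None:
            cand.distance_to_gene = distance_to_gene(cand, gene)
        candidates.append(cand)
    candidates.sort(key=lambda c: c.interval.start)
    return candidates


def classify_candidate(candidate: CandidateRegion) -> RegionClass:
    """Promoter-like beats enhancer-like: H3K4me3 or an active-promoter
    ChromHMM state marks an active promoter; otherwise H3K4me1/H3K27ac or an
    enhancer call marks an enhancer."""
    classes = candidate.evidence_classes()
    if TrackClass.H3K4ME3 in classes:
        return RegionClass.PROMOTER_LIKE
    if any("promoter" in f.name.lower()
           for f in candidate.features_of(TrackClass.CHROMHMM)):
        return RegionClass.PROMOTER_LIKE
    if classes & {TrackClass.H3K4ME1, TrackClass.H3K27AC, TrackClass.ENHANCER,
                  TrackClass.CHROMHMM}:
        return RegionClass.ENHANCER_LIKE
    return RegionClass.UNCLASSIFIED


def distance_to_gene(candidate: CandidateRegion, gene: GenomicInterval) -> int:
    """Signed bp between nearest edges: negative upstream of the gene start,
    positive downstream of the gene end, 0 when overlapping."""
    iv = candidate.interval
    if iv.chrom != gene.chrom:
        raise CoordinateError(
            f"candidate on {iv.chrom} but gene on {gene.chrom}")
    if iv.overlaps(gene):
        return 0
    if iv.end <= gene.start:
        return iv.end - gene.start
    return iv.start - gene.end
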