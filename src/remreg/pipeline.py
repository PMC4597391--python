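"""Orchestration of the six-step prediction procedure.

``predict`` runs Steps 1-5 (binning, gene location, interaction ranking,
CTCF refinement, evidence integration), ``validate`` runs Step 6 against
chromatin-loop calls per source, and ``annotate`` maps variants into the
predicted regions. Each function logs the numbers it derives at INFO and
contributes a section to the JSON report.

The interacting-bin set that bounds Step 4 is taken from the coarse (1-Mb
scale by default) ranking: the gene bins plus every bin whose total contact
count with them reaches ``min_interaction_count``. The fine map, when given,
feeds the exhaustive per-bin summary in the report so weakly interacting
fragments (the "background ceiling") remain visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .core import GenomicInterval
from .ctcf_refine import (CtcfSite, SearchRegion, classify_ctcf,
                          refine_search_region)
from .evidence import CandidateRegion, EvidenceConfig, find_candidates
from .hic import ContactMap, gene_bins, interaction_summary, rank_interacting
from .io_formats import (ConservationTrack, FeatureTrack, LoopCall,
                         LoopSource, TrackClass, Variant)
from .loops import LoopValidation, validate_candidate
from .variants import AnnotatedVariant, annotate_variant

logger = logging.getLogger("remreg")

__all__ = ["PipelineParams", "PredictionResult", "predict", "validate",
           "annotate", "default_promoter"]


@dataclass
class PipelineParams:
    """All tunables of the procedure, with worked-example defaults."""

    bin_size_coarse: int = 1_000_000
    bin_size_fine: int = 100_000
    min_interaction_count: int = 100
    ctcf_threshold: int = 500
    ctcf_merge_gap: int = 5_000
    boundary_policy: str = "outermost"
    cluster_gap: int = 200
    min_mark_classes: int = 1
    primary_cell_line: str = ""
    min_separation: int = 20_000

    def __post_init__(self) -> None:
        if self.bin_size_coarse % self.bin_size_fine != 0:
            raise ValueError(
                f"coarse bin size {self.bin_size_coarse} must be a multiple of "
                f"fine bin size {self.bin_size_fine}")


@dataclass
class PredictionResult:
    gene: GenomicInterval
    gene_bin_starts: list[int]
    ranking: list[tuple[int, int]]
    interacting_bins: list[GenomicInterval]
    search_region: SearchRegion
    candidates: list[CandidateRegion]
    fine_summary: list[tuple[int, int]] = field(default_factory=list)

    def to_report(self) -> dict:
        gs, ge = self.gene.to_printed()
        return {
            "gene": {"chrom": self.gene.chrom, "start_1based": gs, "end_1based": ge},
            "gene_bins": self.gene_bin_starts,
            "interaction_ranking": [
                {"bin_start": b, "total_count": c} for b, c in self.ranking],
            "interacting_bins": [
                [iv.start, iv.end] for iv in self.interacting_bins],
            "fine_scale_summary": [
                {"bin_start": b, "total_count": c} for b, c in self.fine_summary],
            "search_region": self.search_region.to_dict(),
            "candidates": [c.to_dict() for c in self.candidates],
        }


def select_ctcf_sites(tracks: Sequence[FeatureTrack], threshold: int,
                      primary_cell_line: str = "") -> list[CtcfSite]:
    """Classify CTCF features; when a primary cell line is configured and
    represented in the track, restrict to it, else use all sites."""
    feats = [f for t in tracks if t.track_class is TrackClass.CTCF
             for f in t.features]
    if primary_cell_line:
        in_primary = [f for f in feats if f.cell_line == primary_cell_line]
        if in_primary:
            feats = in_primary
    return [classify_ctcf(f, threshold) for f in feats]


def predict(gene: GenomicInterval, contacts_coarse: ContactMap,
            tracks: Sequence[FeatureTrack],
            contacts_fine: ContactMap | None = None,
            params: PipelineParams | None = None) -> PredictionResult:
    """Steps 1-5: from contact map and tracks to candidate regions."""
    params = params or PipelineParams()

    bins = gene_bins(gene, contacts_coarse.bin_size)
    logger.info("Step 1-2: bin size %d bp; gene %s occupies bin(s) %s",
                contacts_coarse.bin_size, gene, bins)

    ranking = rank_interacting(contacts_coarse, bins, min_count=0,
                               include_self=True)
    top = ranking.ranked[:5]
    logger.info("Step 3: top interacting bins %s", top)
    selected = sorted({b for b, c in ranking.ranked
                       if c >= params.min_interaction_count} | set(bins))
    interacting = [contacts_coarse.bin_interval(b) for b in selected]

    ctcf_sites = select_ctcf_sites(tracks, params.ctcf_threshold,
                                   params.primary_cell_line)
    region = refine_search_region(gene, interacting, ctcf_sites,
                                  policy=params.boundary_policy,
                                  merge_gap=params.ctcf_merge_gap)
    logger.info("Step 4: search region %s (%s)", region.interval, region.rationale)

    evidence_tracks = [t for t in tracks if t.track_class is not TrackClass.CTCF]
    cfg = EvidenceConfig(cluster_gap=params.cluster_gap,
                         min_mark_classes=params.min_mark_classes,
                         primary_cell_line=params.primary_cell_line)
    if any(t.track_class in (TrackClass.TFBS, TrackClass.DNASE)
           for t in evidence_tracks):
        candidates = find_candidates(region, evidence_tracks, cfg, gene=gene)
    else:
        logger.warning("Step 5: no TFBS/DNase track supplied; no candidates emitted")
        candidates = []
    for cand in candidates:
        logger.info("Step 5: candidate %s (%s), %.1f kb from gene",
                    cand.interval, cand.region_class.value,
                    (cand.distance_to_gene or 0) / 1000)

    fine_rows: list[tuple[int, int]] = []
    if contacts_fine is not None:
        fbins = gene_bins(gene, contacts_fine.bin_size)
        df = interaction_summary(contacts_fine, fbins)
        fine_rows = list(df.itertuples(index=False, name=None))

    return PredictionResult(gene, bins, ranking.ranked, interacting, region,
                            candidates, fine_rows)


def default_promoter(gene: GenomicInterval,
                     tracks: Sequence[FeatureTrack]) -> GenomicInterval:
    """The H3K4me3-supported promoter interval over the gene start when one
    exists, else gene start +/- 2 kb."""
    for track in tracks:
        if track.track_class is TrackClass.H3K4ME3:
            for feat in track.features:
                if feat.interval.contains_position(gene.start + 1):
                    return feat.interval
    return GenomicInterval(gene.chrom, max(0, gene.start - 2_000), gene.start + 2_000)


def validate(candidates: Sequence[CandidateRegion], promoter: GenomicInterval,
             loop_calls: Sequence[LoopCall],
             min_separation: int = 20_000) -> list[LoopValidation]:
    """Step 6: assess every candidate against each loop source present.

    Sources with no loop calls at all are still assessed (capture Hi-C may
    legitimately report nothing for near-promoter candidates)."""
    results = []
    for cand in candidates:
        for source in LoopSource:
            lv = validate_candidate(cand, promoter, loop_calls,
                                    min_separation=min_separation, source=source)
            logger.info("Step 6: candidate %s vs %s -> %s",
                        cand.interval, source.value, lv.status.value)
            results.append(lv)
    return results


def annotate(variants: Sequence[Variant], candidates: Sequence[CandidateRegion],
             tracks: Sequence[FeatureTrack], known: Sequence[Variant] = (),
             conservation: ConservationTrack | None = None,
             conserved_threshold: float = 0.0) -> list[AnnotatedVariant]:
    """Annotate each variant against the predicted regions and tracks."""
    evidence_tracks = [t for t in tracks if t.track_class is not TrackClass.CTCF]
    out = []
    for v in variants:
        av = annotate_variant(v, candidates, evidence_tracks, known,
                              conservation, conserved_threshold)
        logger.info("variant %s:%d %s>%s: %d candidate(s), %d feature overlap(s),"
                    " conserved=%s, novel=%s", v.chrom, v.pos, v.ref, v.alt,
                    len(av.containing_candidates), len(av.overlapping_features),
                    av.conserved, av.novel)
        out.append(av)
    return out
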