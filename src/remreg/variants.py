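"""Annotation of patient variants falling inside predicted regions.

Each variant (a 1-bp interval at its printed position) is annotated with the
candidate regions containing it, the scored features it overlaps (DNase
clusters, TFBSs, marks), its per-base conservation score with a
conserved/not-conserved label, and novelty against a user-supplied
known-variant list (e.g. a dbSNP extract) — no online lookups.

Also houses two small cohort utilities: exact allele tallies/frequencies at
a position across a patient cohort, and the bisulphite methylation average
over a fixed panel of validated CpG sites.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

from .core import CoordinateError, GenomicInterval, intersect_all
from .evidence import CandidateRegion
from .io_formats import ConservationTrack, FeatureTrack, ScoredFeature, TrackClass, Variant

__all__ = ["AnnotatedVariant", "CohortSummary", "MethylationProfile",
           "annotate_variant", "conservation_label", "cohort_summary",
           "mean_methylation"]


@dataclass
class AnnotatedVariant:
    variant: Variant
    containing_candidates: list[CandidateRegion] = field(default_factory=list)
    overlapping_features: list[tuple[TrackClass, ScoredFeature]] = field(default_factory=list)
    conservation_score: float | None = None
    conserved: bool | None = None
    novel: bool = True

    def feature_names(self, cls: TrackClass) -> list[str]:
        return [f.name for c, f in self.overlapping_features if c is cls]

    def to_dict(self) -> dict:
        v = self.variant
        return {
            "chrom": v.chrom,
            "pos_1based": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "zygosity": v.zygosity.value,
            "novel": self.novel,
            "in_candidates": [list(c.interval.to_printed()) for c in self.containing_candidates],
            "overlapping_features": [
                {"track_class": cls.value, "name": f.name, "score": f.score,
                 "start_1based": f.interval.to_printed()[0],
                 "end_1based": f.interval.to_printed()[1]}
                for cls, f in self.overlapping_features
            ],
            "conservation_score": self.conservation_score,
            "conserved": self.conserved,
        }


def conservation_label(score: float, threshold: float = 0.0) -> bool:
    """Conserved iff the per-base score exceeds *threshold*.

    The default follows phyloP semantics: positive scores indicate
    slower-than-neutral (conserved) sites, negative scores acceleration.
    """
    return score > threshold


def annotate_variant(
    variant: Variant,
    candidates: Sequence[CandidateRegion],
    tracks: Sequence[FeatureTrack],
    known: Sequence[Variant] = (),
    conservation: ConservationTrack | None = None,
    conserved_threshold: float = 0.0,
) -> AnnotatedVariant:
    """Annotate one variant by interval algebra against candidates and tracks."""
    point = variant.interval
    containing = [c for c in candidates if c.interval.contains(point)]
    overlapping: list[tuple[TrackClass, ScoredFeature]] = []
    for track in tracks:
        for feat in intersect_all(point, track.features):
            overlapping.append((track.track_class, feat))
    score = conservation.value_at(variant.chrom, variant.pos) if conservation else None
    return AnnotatedVariant(
        variant=variant,
        containing_candidates=list(containing),
        overlapping_features=overlapping,
        conservation_score=score,
        conserved=None if score is None else conservation_label(score, conserved_threshold),
        novel=variant.key() not in {k.key() for k in known},
    )


@dataclass
class CohortSummary:
    """Exact allele tallies at one position across a patient cohort."""

    position: int
    allele_counts: dict[str, int]
    n: int
    frequencies: dict[str, Fraction]

    def to_dict(self) -> dict:
        return {
            "position": self.position,
            "n": self.n,
            "allele_counts": dict(self.allele_counts),
            "frequencies": {a: float(f) for a, f in self.frequencies.items()},
        }


def cohort_summary(position: int, calls: Sequence[str]) -> CohortSummary:
    """Tally per-patient allele calls at a position; frequencies are exact
    rationals so they sum to 1 identically."""
    if not calls:
        raise ValueError("cohort allele calls must be non-empty")
    counts = Counter(calls)
    n = len(calls)
    freqs = {allele: Fraction(c, n) for allele, c in sorted(counts.items())}
    return CohortSummary(position, dict(sorted(counts.items())), n, freqs)


@dataclass
class MethylationProfile:
    """Bisulphite C-vs-T ratios at a fixed panel of validated CpG sites."""

    site_ratios: list[float]
    n_sites: int = 10

    def __post_init__(self) -> None:
        if len(self.site_ratios) != self.n_sites:
            raise ValueError(
                f"expected {self.n_sites} site ratios, got {len(self.site_ratios)}")
        bad = [r for r in self.site_ratios if not (0.0 <= r <= 1.0)]
        if bad:
            raise ValueError(f"C/T ratios must lie in [0, 1]; got {bad}")


def mean_methylation(profile: MethylationProfile) -> int:
    """Average the per-site C-vs-T ratios and report an integer percent."""
    mean = sum(profile.site_ratios) / profile.n_sites
    return round(mean * 100)
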