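"""Chromatin-loop validation of candidate regions (procedure Step 6).

A candidate is *supported* when some loop call joins it to the gene promoter
(one anchor overlapping each, in either orientation). Capture Hi-C datasets
typically report only promoter interactions with fragments separated by more
than ~20 kb, so a candidate closer to the promoter than ``min_separation``
that finds no capture-Hi-C loop is *not assessable* by that source rather
than unsupported. Loop scores, when present in the input, are carried
through but never thresholded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .core import CoordinateError, GenomicInterval
from .evidence import CandidateRegion
from .io_formats import LoopCall, LoopSource

__all__ = ["ValidationStatus", "LoopValidation", "validate_candidate",
           "DEFAULT_MIN_SEPARATION"]

DEFAULT_MIN_SEPARATION = 20_000  # bp; capture-Hi-C reporting floor


class ValidationStatus(Enum):
    SUPPORTED = "supported"
    UNSUPPORTED = "unsupported"
    NOT_ASSESSABLE = "not_assessable"


@dataclass
class LoopValidation:
    candidate: CandidateRegion
    status: ValidationStatus
    matching_loops: list[LoopCall] = field(default_factory=list)
    separation: int = 0  # bp between candidate and promoter nearest edges
    source: LoopSource | None = None

    def to_dict(self) -> dict:
        s, e = self.candidate.interval.to_printed()
        return {
            "candidate_start_1based": s,
            "candidate_end_1based": e,
            "status": self.status.value,
            "source": self.source.value if self.source else "any",
            "separation_bp": self.separation,
            "matching_loops": [
                {"anchor_a": [lp.anchor_a.start, lp.anchor_a.end],
                 "anchor_b": [lp.anchor_b.start, lp.anchor_b.end],
                 "source": lp.source.value, "resolution": lp.resolution,
                 "score": lp.score}
                for lp in self.matching_loops
            ],
        }


def _joins(loop: LoopCall, candidate: GenomicInterval, promoter: GenomicInterval) -> bool:
    return (
        (loop.anchor_a.overlaps(candidate) and loop.anchor_b.overlaps(promoter))
        or (loop.anchor_b.overlaps(candidate) and loop.anchor_a.overlaps(promoter))
    )


def validate_candidate(
    candidate: CandidateRegion,
    promoter: GenomicInterval,
    loop_calls: Sequence[LoopCall],
    min_separation: int = DEFAULT_MIN_SEPARATION,
    source: LoopSource | None = None,
) -> LoopValidation:
    """Assess one candidate against loop calls from one (or any) source.

    Parameters
    ----------
    source : LoopSource or None
        The dataset being consulted. When ``capture_hic``, candidates within
        ``min_separation`` of the promoter that lack a supporting loop are
        ``not_assessable`` (the dataset cannot see them); for any other
        source they are ``unsupported``. ``None`` uses every supplied loop
        and applies no reporting-floor rule.
    """
    if promoter is None:
        raise ValueError("promoter interval is required")
    if promoter.chrom != candidate.interval.chrom:
        raise CoordinateError(
            f"promoter on {promoter.chrom} but candidate on {candidate.interval.chrom}")
    loops = [lp for lp in loop_calls if source is None or lp.source is source]
    matches = [lp for lp in loops if _joins(lp, candidate.interval, promoter)]
    separation = candidate.interval.gap_to(promoter)
    if matches:
        status = ValidationStatus.SUPPORTED
    elif source is LoopSource.CAPTURE_HIC and separation <= min_separation:
        status = ValidationStatus.NOT_ASSESSABLE
    else:
        status = ValidationStatus.UNSUPPORTED
    return LoopValidation(candidate, status, matches, separation, source)
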