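"""Readers and writers for the standard formats the pipeline touches.

Supported on input: BED3/BED6, ENCODE narrowPeak, BEDPE (chromatin loop
calls), VCF 4.x (via pysam), bedGraph (per-base conservation scores) and a
4-column tab-separated contact table (chrom, bin_i_start, bin_j_start,
count) for pre-binned intra-chromosomal Hi-C counts. BED-family coordinates
are 0-based half-open and preserved bit-exactly; VCF positions are 1-based.

Malformed lines raise :class:`ParseError` naming the offending line number
(VCF errors carry pysam's message instead). Empty files yield empty
containers, not errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import pysam

from .core import GenomicInterval, Strand

__all__ = [
    "TrackClass",
    "ScoredFeature",
    "FeatureTrack",
    "LoopCall",
    "LoopSource",
    "Variant",
    "Zygosity",
    "ConservationTrack",
    "ParseError",
    "read_bed",
    "read_narrowpeak",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_contacts",
    "write_contacts",
    "read_loops_bedpe",
    "write_loops_bedpe",
    "read_vcf",
    "write_vcf",
    "write_candidates_bed",
    "write_report_json",
]


class ParseError(ValueError):
    """A malformed record in an input file."""


class TrackClass(Enum):
    """Closed set of feature-track classes consumed by evidence integration."""

    CTCF = "CTCF"
    H3K4ME1 = "H3K4me1"
    H3K4ME3 = "H3K4me3"
    H3K27AC = "H3K27ac"
    DNASE = "DNase"
    TFBS = "TFBS"
    ENHANCER = "ENHANCER"
    CHROMHMM = "CHROMHMM"
    CONSERVATION = "CONSERVATION"

    @classmethod
    def parse(cls, text: str) -> "TrackClass":
        for member in cls:
            if member.value.lower() == text.lower() or member.name.lower() == text.lower():
                return member
        raise ParseError(f"unknown track class {text!r}; expected one of "
                         f"{[m.value for m in cls]}")


@dataclass(frozen=True)
class ScoredFeature:
    """A scored genomic feature (ENCODE-style 0-1000 score)."""

    interval: GenomicInterval
    name: str = "."
    score: int = 0
    cell_line: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.score <= 1000):
            raise ParseError(f"feature score {self.score} outside 0-1000")


@dataclass
class FeatureTrack:
    """A typed collection of scored features, tagged with a cell line."""

    track_class: TrackClass
    features: list[ScoredFeature] = field(default_factory=list)
    cell_line: str = ""

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)


class LoopSource(Enum):
    IN_SITU_HIC = "in_situ_hic"
    CAPTURE_HIC = "capture_hic"


@dataclass(frozen=True)
class LoopCall:
    """A called chromatin looping interaction between two anchors."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    source: LoopSource
    resolution: int = 5000
    score: float | None = None  # carried through, never thresholded

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ParseError(f"loop resolution must be positive, got {self.resolution}")


class Zygosity(Enum):
    HET = "het"
    HOM = "hom"
    MOSAIC = "mosaic"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Variant:
    """A sequence variant at a 1-based position (SNVs in this pipeline)."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    zygosity: Zygosity = Zygosity.UNKNOWN

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ParseError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ParseError(f"ref and alt alleles identical ({self.ref}) at {self.pos}")

    @property
    def interval(self) -> GenomicInterval:
        """The variant as a 1-bp half-open interval."""
        return GenomicInterval(self.chrom, self.pos - 1, self.pos)

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ConservationTrack:
    """Per-base conservation scores (e.g. phyloP) as (interval, value) pairs."""

    records: list[tuple[GenomicInterval, float]] = field(default_factory=list)

    def value_at(self, chrom: str, pos_1based: int) -> float | None:
        for iv, value in self.records:
            if iv.chrom == chrom and iv.start < pos_1based <= iv.end:
                return value
        return None


# ---------------------------------------------------------------------------
# line-oriented parsing helpers

def _lines(path) -> list[tuple[int, str]]:
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track ", "browser ")):
                continue
            out.append((lineno, line))
    return out


def _int_field(path, lineno: int, text: str, what: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer {what}: {text!r}") from None


def _bed_interval(path, lineno: int, cols: Sequence[str]) -> GenomicInterval:
    start = _int_field(path, lineno, cols[1], "start")
    end = _int_field(path, lineno, cols[2], "end")
    try:
        return GenomicInterval(cols[0], start, end)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from None


def read_bed(path, track_class: TrackClass | str, cell_line: str = "") -> FeatureTrack:
    """Read a BED3/BED6 file into a :class:`FeatureTrack`."""
    if isinstance(track_class, str):
        track_class = TrackClass.parse(track_class)
    features = []
    for lineno, line in _lines(path):
        cols = line.split("\t")
        if len(cols) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated columns, "
                             f"got {len(cols)}")
        iv = _bed_interval(path, lineno, cols)
        name = cols[3] if len(cols) > 3 else "."
        score = _int_field(path, lineno, cols[4], "score") if len(cols) > 4 else 0
        if len(cols) > 5 and cols[5] in ("+", "-", "."):
            iv = GenomicInterval(iv.chrom, iv.start, iv.end, Strand(cols[5]))
        try:
            features.append(ScoredFeature(iv, name, score, cell_line))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return FeatureTrack(track_class, features, cell_line)


def read_narrowpeak(path, track_class: TrackClass | str, cell_line: str = "") -> FeatureTrack:
    """Read an ENCODE narrowPeak file (10 columns; only position, name and the
    0-1000 score column are used — signalValue/pValue/qValue/peak are parsed
    for validity but discarded)."""
    if isinstance(track_class, str):
        track_class = TrackClass.parse(track_class)
    features = []
    for lineno, line in _lines(path):
        cols = line.split("\t")
        if len(cols) < 10:
            raise ParseError(f"{path}:{lineno}: narrowPeak needs 10 columns, got {len(cols)}")
        iv = _bed_interval(path, lineno, cols)
        score = _int_field(path, lineno, cols[4], "score")
        try:
            features.append(ScoredFeature(iv, cols[3], score, cell_line))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return FeatureTrack(track_class, features, cell_line)


def write_bed(track: FeatureTrack, path) -> None:
    with open(path, "w") as fh:
        for f in track.features:
            fh.write(f"{f.interval.chrom}\t{f.interval.start}\t{f.interval.end}"
                     f"\t{f.name}\t{f.score}\t{f.interval.strand.value}\n")


def read_bedgraph(path) -> ConservationTrack:
    """Read a bedGraph of per-base scores (4th column is a float value)."""
    records = []
    for lineno, line in _lines(path):
        cols = line.split("\t")
        if len(cols) < 4:
            raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns, got {len(cols)}")
        iv = _bed_interval(path, lineno, cols)
        try:
            value = float(cols[3])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric value {cols[3]!r}") from None
        records.append((iv, value))
    return ConservationTrack(records)


def write_bedgraph(track: ConservationTrack, path) -> None:
    with open(path, "w") as fh:
        for iv, value in track.records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{value:g}\n")


def read_contacts(path, bin_size: int):
    """Read a 4-column contact TSV into a :class:`~remreg.hic.ContactMap`.

    Columns: chrom, bin_i_start, bin_j_start, count. Bin starts must be
    multiples of *bin_size*; counts must be non-negative. The map is stored
    symmetrically: count(i, j) == count(j, i).
    """
    from .hic import ContactMap  # local import to avoid a cycle

    cmap: ContactMap | None = None
    for lineno, line in _lines(path):
        cols = line.split("\t")
        if len(cols) < 4:
            raise ParseError(f"{path}:{lineno}: contact rows need 4 columns, got {len(cols)}")
        chrom = cols[0]
        bin_i = _int_field(path, lineno, cols[1], "bin_i_start")
        bin_j = _int_field(path, lineno, cols[2], "bin_j_start")
        count = _int_field(path, lineno, cols[3], "count")
        for b in (bin_i, bin_j):
            if b % bin_size != 0 or b < 0:
                raise ParseError(f"{path}:{lineno}: bin start {b} is not a "
                                 f"non-negative multiple of bin size {bin_size}")
        if count < 0:
            raise ParseError(f"{path}:{lineno}: negative contact count {count}")
        if cmap is None:
            cmap = ContactMap(chrom=chrom, bin_size=bin_size)
        elif chrom != cmap.chrom:
            raise ParseError(f"{path}:{lineno}: map is intra-chromosomal; found "
                             f"{chrom!r} after {cmap.chrom!r}")
        cmap.set_count(bin_i, bin_j, count)
    if cmap is None:
        cmap = ContactMap(chrom="", bin_size=bin_size)
    return cmap


def write_contacts(cmap, path) -> None:
    with open(path, "w") as fh:
        for (i, j), count in sorted(cmap.counts.items()):
            fh.write(f"{cmap.chrom}\t{i}\t{j}\t{count}\n")


def read_loops_bedpe(path, source: LoopSource | str, resolution: int = 5000) -> list[LoopCall]:
    """Read loop calls from a >= 6-column BEDPE file."""
    if isinstance(source, str):
        source = LoopSource(source)
    loops = []
    for lineno, line in _lines(path):
        cols = line.split("\t")
        if len(cols) < 6:
            raise ParseError(f"{path}:{lineno}: BEDPE needs >= 6 columns, got {len(cols)}")
        a = _bed_interval(path, lineno, cols[0:3])
        b = _bed_interval(path, lineno, cols[3:6])
        score = None
        if len(cols) > 7 and cols[7] not in (".", ""):
            try:
                score = float(cols[7])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric loop score {cols[7]!r}") from None
        loops.append(LoopCall(a, b, source, resolution, score))
    return loops


def write_loops_bedpe(loops: Sequence[LoopCall], path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            score = "." if lp.score is None else f"{lp.score:g}"
            fh.write(f"{lp.anchor_a.chrom}\t{lp.anchor_a.start}\t{lp.anchor_a.end}"
                     f"\t{lp.anchor_b.chrom}\t{lp.anchor_b.start}\t{lp.anchor_b.end}"
                     f"\t.\t{score}\n")


# ---------------------------------------------------------------------------
# VCF

def _zygosity_of(record, sample_values) -> Zygosity:
    if record.info.get("MOSAIC", False):
        return Zygosity.MOSAIC
    gt = sample_values.get("GT") if sample_values is not None else None
    if gt is None or any(a is None for a in gt):
        return Zygosity.UNKNOWN
    alleles = set(gt)
    if alleles == {0}:
        return Zygosity.UNKNOWN  # hom-ref carries no variant zygosity
    return Zygosity.HOM if len(alleles) == 1 else Zygosity.HET


def read_vcf(path) -> list[Variant]:
    """Read a VCF 4.x sites-or-genotypes file into a list of variants.

    Zygosity is taken from the first sample's GT when genotypes are present;
    a truthy ``MOSAIC`` INFO flag overrides it (mosaicism cannot be encoded
    in a diploid GT). Multi-allelic records are split per ALT allele.
    """
    variants = []
    try:
        with pysam.VariantFile(str(path)) as vcf:
            for record in vcf:
                sample_values = None
                if record.samples:
                    sample_values = record.samples[next(iter(record.samples))]
                zyg = _zygosity_of(record, sample_values)
                for alt in record.alts or ():
                    variants.append(Variant(record.chrom, record.pos, record.ref, alt, zyg))
    except (OSError, ValueError) as exc:
        raise ParseError(f"{path}: VCF parse error: {exc}") from None
    return variants


def write_vcf(variants: Sequence[Variant], path, contigs: Sequence[str] = ()) -> None:
    """Write variants as a minimal VCF 4.2 sites file with one sample column
    (GT derived from zygosity; mosaic encoded as 0/1 plus a MOSAIC flag)."""
    chroms = list(dict.fromkeys(list(contigs) + [v.chrom for v in variants]))
    gt_of = {Zygosity.HET: "0/1", Zygosity.HOM: "1/1",
             Zygosity.MOSAIC: "0/1", Zygosity.UNKNOWN: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MOSAIC,Number=0,Type=Flag,Description="Mosaic change">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tproband\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
            info = "MOSAIC" if v.zygosity is Zygosity.MOSAIC else "."
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}"
                     f"\tGT\t{gt_of[v.zygosity]}\n")


# ---------------------------------------------------------------------------
# report output

def write_candidates_bed(candidates, path) -> None:
    """Write candidate regulatory regions as BED6 (class label in the name
    column) with a JSON evidence sidecar next to it."""
    path = Path(path)
    with open(path, "w") as fh:
        for idx, cand in enumerate(candidates, start=1):
            iv = cand.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}"
                     f"\tcandidate_{idx}|{cand.region_class.value}\t0\t.\n")
    sidecar = path.with_suffix(path.suffix + ".evidence.json")
    write_report_json({"candidates": [cand.to_dict() for cand in candidates]}, sidecar)


REPORT_SCHEMA_VERSION = "1.0"


def write_report_json(report: dict, path) -> None:
    payload = {"schema_version": REPORT_SCHEMA_VERSION}
    payload.update(report)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
        fh.write("\n")
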