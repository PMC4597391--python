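"""Synthetic-data generation: the worked SMCHD1 example locus and randomized
loci with planted regulatory elements.

:func:`paper_locus` rebuilds, from published hg18 coordinates, the chr18
SMCHD1 locus used as the package's worked example: the 1-Mb/100-kb Hi-C
contact counts, the flanking CTCF sites, the ENCODE/FANTOM mark, DNase, TFBS,
enhancer and ChromHMM calls, the in situ Hi-C promoter loop, and the three
patient variants found ~14 kb upstream of the gene. Where a feature is named
in the published record without printed coordinates (the BATF/SPI1 binding
sites, the distal TFBS/DNase anchors and the distal H3K4me3 interval), a
synthetic span consistent with the printed enclosing region is used; those
features are marked ``synthetic`` below.

:func:`random_locus` generates a seeded random locus with one planted
regulatory element (co-occurring TFBS cluster, DNase peak, histone mark and
a chromatin loop to the gene promoter) plus decoy regions that each lack a
required evidence class, over a background of weak Hi-C contacts. The
planted coordinates are returned so end-to-end tests can check exact
recovery.

Everything can be serialized to the standard on-disk formats (BED, BEDPE,
VCF, bedGraph, contact TSV) plus a YAML pipeline config via
:func:`write_bundle`, so CLI tests consume real files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import CoordinateError, GenomicInterval
from .hic import ContactMap, gene_bins
from .io_formats import (ConservationTrack, FeatureTrack, LoopCall, LoopSource,
                         ScoredFeature, TrackClass, Variant, Zygosity,
                         write_bed, write_bedgraph, write_contacts,
                         write_loops_bedpe, write_vcf)
from .variants import MethylationProfile

__all__ = ["LocusBundle", "SimulationConfig", "paper_locus", "random_locus",
           "write_bundle"]

_P = GenomicInterval.from_printed  # 1-based inclusive -> internal half-open


@dataclass
class LocusBundle:
    """Everything the pipeline consumes for one locus, in memory."""

    chrom: str
    gene: GenomicInterval
    promoter: GenomicInterval
    contacts_coarse: ContactMap
    contacts_fine: ContactMap
    tracks: list[FeatureTrack]
    loops: list[LoopCall]
    variants: list[Variant]
    known_variants: list[Variant]
    conservation: ConservationTrack
    cohort_position: int
    cohort_calls: list[str]
    methylation: MethylationProfile
    planted_region: GenomicInterval | None = None
    decoy_regions: list[GenomicInterval] = field(default_factory=list)

    def tracks_of(self, cls: TrackClass) -> list[FeatureTrack]:
        return [t for t in self.tracks if t.track_class is cls]

    def evidence_tracks(self) -> list[FeatureTrack]:
        return [t for t in self.tracks if t.track_class is not TrackClass.CTCF]


def paper_locus() -> LocusBundle:
    """The worked-example SMCHD1 locus (chr18, hg18), byte-identical across runs."""
    chrom = "chr18"
    gene = _P(2_645_885, 2_795_015, chrom)  # SMCHD1 gene span
    # 5-kb in situ Hi-C anchor over the SMCHD1 promoter region
    promoter = GenomicInterval(chrom, 2_640_000, 2_645_000)

    # 1-Mb contacts: the gene-containing bin interacts most strongly with
    # itself (3371) and the adjacent downstream bin (663); elsewhere <= 30.
    coarse = ContactMap(chrom, 1_000_000)
    coarse.set_count(2_000_000, 2_000_000, 3371)
    coarse.set_count(2_000_000, 3_000_000, 663)
    for b, c in ((0, 28), (1_000_000, 25), (4_000_000, 12), (5_000_000, 7),
                 (7_000_000, 3)):
        coarse.set_count(2_000_000, b, c)

    # 100-kb contacts: the two gene fragments self-interact (256, 237); the
    # 2.5-Mb bin totals 23 with the gene fragments; all others <= 30.
    fine = ContactMap(chrom, 100_000)
    fine.set_count(2_600_000, 2_600_000, 256)
    fine.set_count(2_700_000, 2_700_000, 237)
    fine.set_count(2_600_000, 2_700_000, 29)
    fine.set_count(2_500_000, 2_600_000, 13)
    fine.set_count(2_500_000, 2_700_000, 10)
    fine.set_count(2_400_000, 2_600_000, 9)
    fine.set_count(2_400_000, 2_700_000, 6)
    fine.set_count(2_600_000, 2_800_000, 12)
    fine.set_count(2_700_000, 2_800_000, 14)
    fine.set_count(2_700_000, 2_900_000, 18)

    gm = "GM06990"
    ctcf = FeatureTrack(TrackClass.CTCF, [
        # two weak sites clustered between 2,531,952 and 2,537,783 ...
        ScoredFeature(_P(2_531_952, 2_532_420, chrom), "CTCF", 440, gm),
        ScoredFeature(_P(2_537_300, 2_537_783, chrom), "CTCF", 420, gm),
        # ... and one strong site at 2,922,164-2,922,551 (score 719/1000)
        ScoredFeature(_P(2_922_164, 2_922_551, chrom), "CTCF", 719, gm),
    ], gm)

    h3k4me1_gm12878 = FeatureTrack(TrackClass.H3K4ME1, [
        ScoredFeature(_P(2_624_475, 2_635_775, chrom), "H3K4me1", 600, "GM12878"),
    ], "GM12878")
    h3k27ac_gm12878 = FeatureTrack(TrackClass.H3K27AC, [
        ScoredFeature(_P(2_624_475, 2_635_775, chrom), "H3K27ac", 620, "GM12878"),
    ], "GM12878")
    # distal H3K4me1/H3K27ac span seen in the non-GM12878 cell lines
    h3k4me1_k562 = FeatureTrack(TrackClass.H3K4ME1, [
        ScoredFeature(_P(2_557_575, 2_566_775, chrom), "H3K4me1", 540, "K562"),
    ], "K562")
    h3k27ac_k562 = FeatureTrack(TrackClass.H3K27AC, [
        ScoredFeature(_P(2_557_575, 2_566_775, chrom), "H3K27ac", 560, "K562"),
    ], "K562")
    h3k4me3 = FeatureTrack(TrackClass.H3K4ME3, [
        # active-promoter mark over the gene's own promoter region
        ScoredFeature(_P(2_644_486, 2_648_785, chrom), "H3K4me3", 700, gm),
        # distal H3K4me3 enrichment at the METTL4 promoter (synthetic span)
        ScoredFeature(_P(2_560_500, 2_563_000, chrom), "H3K4me3", 650, gm),
    ], gm)

    dnase = FeatureTrack(TrackClass.DNASE, [
        # DNaseI hypersensitive cluster, score 976/1000
        ScoredFeature(_P(2_631_700, 2_631_930, chrom), "DHS", 976, gm),
        # distal DNase peak under the sequenced region (synthetic span)
        ScoredFeature(_P(2_561_700, 2_562_509, chrom), "DHS", 850, gm),
    ], gm)

    tfbs = FeatureTrack(TrackClass.TFBS, [
        ScoredFeature(_P(2_631_639, 2_632_023, chrom), "IRF1", 1000, gm),
        ScoredFeature(_P(2_631_540, 2_632_016, chrom), "STAT1", 1000, gm),
        ScoredFeature(_P(2_631_654, 2_632_010, chrom), "STAT2", 1000, gm),
        ScoredFeature(_P(2_631_672, 2_631_955, chrom), "RUNX3", 1000, gm),
        # BATF/SPI1 sites sit in the same enriched region; synthetic spans
        # chosen so the cluster spans exactly 2,631,527-2,632,188
        ScoredFeature(_P(2_631_527, 2_631_940, chrom), "BATF", 820, gm),
        ScoredFeature(_P(2_631_760, 2_632_188, chrom), "SPI1", 780, gm),
        # distal anchor site at the METTL4 promoter (synthetic span)
        ScoredFeature(_P(2_561_489, 2_561_950, chrom), "SP1", 640, gm),
        # decoy: a lone TFBS with no corroborating marks
        ScoredFeature(_P(2_590_001, 2_590_400, chrom), "ZNF143", 520, gm),
    ], gm)

    enhancer = FeatureTrack(TrackClass.ENHANCER, [
        # strong enhancer call at 2,631,000-2,632,200
        ScoredFeature(_P(2_631_000, 2_632_200, chrom), "enhancer", 900, ""),
    ], "")
    chromhmm = FeatureTrack(TrackClass.CHROMHMM, [
        # active promoter state over the METTL4 promoter
        ScoredFeature(_P(2_560_200, 2_563_800, chrom), "Active_Promoter", 0, "GM12878"),
    ], "GM12878")

    loops = [
        # strong looping interaction between the promoter 5-kb fragment and
        # the 5-kb fragment harbouring the three variants (GM12878)
        LoopCall(GenomicInterval(chrom, 2_630_000, 2_635_000),
                 GenomicInterval(chrom, 2_640_000, 2_645_000),
                 LoopSource.IN_SITU_HIC, 5000),
    ]

    variants = [
        Variant(chrom, 2_631_610, "T", "C", Zygosity.HET),
        Variant(chrom, 2_631_858, "T", "C", Zygosity.HET),
        Variant(chrom, 2_631_886, "G", "A", Zygosity.HET),
    ]
    # rs7229070: the 2,631,858 T/C polymorphism is a known SNP; the other
    # two changes are novel
    known = [Variant(chrom, 2_631_858, "T", "C", Zygosity.UNKNOWN)]

    conservation = ConservationTrack([
        (_P(2_631_610, 2_631_610, chrom), 0.557),
        (_P(2_631_858, 2_631_858, chrom), 0.691),
        (_P(2_631_886, 2_631_886, chrom), 0.431),
    ])

    return LocusBundle(
        chrom=chrom, gene=gene, promoter=promoter,
        contacts_coarse=coarse, contacts_fine=fine,
        tracks=[ctcf, h3k4me1_gm12878, h3k4me1_k562, h3k27ac_gm12878,
                h3k27ac_k562, h3k4me3, dnase, tfbs, enhancer, chromhmm],
        loops=loops, variants=variants, known_variants=known,
        conservation=conservation,
        # 182 of 229 patients carried the C allele, 47 the T allele
        cohort_position=2_631_858,
        cohort_calls=["C"] * 182 + ["T"] * 47,
        # ten validated bisulphite sites averaging to 24 % methylation
        methylation=MethylationProfile([0.24] * 10),
    )


@dataclass
class SimulationConfig:
    """Conditions for a randomized locus with one planted element.

    Background contact counts are uniform on [0, background_count_max]
    (default 30, the background ceiling of the worked example) while the
    planted bin carries 663 contacts with the gene bin and the gene bin 3371
    with itself, echoing the worked example's contrast.
    """

    seed: int
    chrom_length: int = 10_000_000
    bin_size: int = 100_000
    n_decoy_regions: int = 3
    planted_region: GenomicInterval | None = None
    background_count_max: int = 30
    planted_counts: dict[int, int] | None = None
    cohort_size: int = 229

    def __post_init__(self) -> None:
        if self.background_count_max >= 663:
            raise ValueError("background ceiling must stay below planted counts")
        if self.planted_region is not None and (
                self.planted_region.start < 0
                or self.planted_region.end > self.chrom_length):
            raise CoordinateError("planted region outside the chromosome")


def random_locus(config: SimulationConfig) -> LocusBundle:
    """A seeded random locus; same seed, identical bundle."""
    rng = np.random.default_rng(config.seed)
    chrom = "chrS"
    L, bs = config.chrom_length, config.bin_size

    gene_start = int(rng.integers(L * 3 // 5, L * 4 // 5))
    gene = GenomicInterval(chrom, gene_start, gene_start + 150_000)
    promoter = GenomicInterval(chrom, gene.start - 2_000, gene.start + 2_000)

    if config.planted_region is not None:
        planted = config.planted_region
    else:
        offset = int(rng.integers(50_000, 800_000))
        width = int(rng.integers(600, 1_500))
        planted = GenomicInterval(chrom, gene.start - offset - width,
                                  gene.start - offset)
    if planted.start < 0 or planted.end > L:
        raise CoordinateError("planted region outside the chromosome")

    # CTCF boundaries framing the search region
    up_start = max(0, planted.start - int(rng.integers(10_000, 40_000)))
    down_start = min(L - 500, gene.end + int(rng.integers(5_000, 50_000)))
    ctcf = FeatureTrack(TrackClass.CTCF, [
        ScoredFeature(GenomicInterval(chrom, up_start, up_start + 400),
                      "CTCF", int(rng.integers(300, 450)), "SIM"),
        ScoredFeature(GenomicInterval(chrom, down_start, down_start + 400),
                      "CTCF", int(rng.integers(700, 900)), "SIM"),
    ], "SIM")

    # contacts: gene self-bins strong, bins across the CTCF span above the
    # ranking threshold, planted bin at 663, background uniform [0, max]
    g_bins = gene_bins(gene, bs)
    cmap = ContactMap(chrom, bs)
    for g in g_bins:
        cmap.set_count(g, g, 3371)
    planted_bin = planted.start // bs * bs
    span_bins = range(up_start // bs * bs, down_start // bs * bs + bs, bs)
    for b in span_bins:
        if b not in g_bins:
            cmap.set_count(g_bins[0], b, int(rng.integers(150, 400)))
    overrides = config.planted_counts or {planted_bin: 663}
    for b, c in overrides.items():
        cmap.set_count(g_bins[0], b, c)
    for _ in range(40):
        b = int(rng.integers(0, L // bs)) * bs
        if b in g_bins or b in span_bins:
            continue
        cmap.set_count(g_bins[0], b, int(rng.integers(0, config.background_count_max + 1)))

    # planted element: TFBS cluster spanning exactly the planted interval,
    # a DNase peak inside it, and an H3K27ac mark over it
    ps, pe = planted.start, planted.end
    w = pe - ps
    tfbs_feats = [
        ScoredFeature(GenomicInterval(chrom, ps, ps + max(2, 2 * w // 3)),
                      "TF1", int(rng.integers(700, 1001)), "SIM"),
        ScoredFeature(GenomicInterval(chrom, ps + w // 3, pe),
                      "TF2", int(rng.integers(700, 1001)), "SIM"),
        ScoredFeature(GenomicInterval(chrom, ps + w // 4, ps + max(2, 3 * w // 4)),
                      "TF3", int(rng.integers(700, 1001)), "SIM"),
    ]
    dnase_feats = [ScoredFeature(GenomicInterval(chrom, ps + 5, pe - 5),
                                 "DHS", int(rng.integers(700, 1001)), "SIM")]
    mark_feats = [ScoredFeature(GenomicInterval(chrom, ps - 500, pe + 500),
                                "H3K27ac", 600, "SIM")]
    h3k4me3_feats = [ScoredFeature(
        GenomicInterval(chrom, gene.start - 1_500, gene.start + 1_500),
        "H3K4me3", 700, "SIM")]

    # decoys between the planted element and the gene: alternately an
    # anchor with no marks and marks with no anchor
    decoys: list[GenomicInterval] = []
    lo, hi = pe + 3_000, gene.start - 6_000
    if config.n_decoy_regions:
        spacing = max(2_000, (hi - lo) // max(1, config.n_decoy_regions))
        for i in range(config.n_decoy_regions):
            d_start = lo + i * spacing
            d = GenomicInterval(chrom, d_start, d_start + 800)
            decoys.append(d)
            if i % 2 == 0:
                tfbs_feats.append(ScoredFeature(d, f"decoyTF{i}",
                                                int(rng.integers(500, 900)), "SIM"))
            else:
                mark_feats.append(ScoredFeature(d, "H3K27ac", 500, "SIM"))

    tracks = [
        ctcf,
        FeatureTrack(TrackClass.TFBS, tfbs_feats, "SIM"),
        FeatureTrack(TrackClass.DNASE, dnase_feats, "SIM"),
        FeatureTrack(TrackClass.H3K27AC, mark_feats, "SIM"),
        FeatureTrack(TrackClass.H3K4ME3, h3k4me3_feats, "SIM"),
    ]

    res = 5_000
    a0 = (ps + pe) // 2 // res * res
    b0 = gene.start // res * res
    loops = [LoopCall(GenomicInterval(chrom, a0, a0 + res),
                      GenomicInterval(chrom, b0, b0 + res),
                      LoopSource.IN_SITU_HIC, res)]
    if planted.gap_to(promoter) > 20_000:
        loops.append(LoopCall(GenomicInterval(chrom, a0, a0 + res),
                              GenomicInterval(chrom, b0, b0 + res),
                              LoopSource.CAPTURE_HIC, res))

    bases = np.array(["A", "C", "G", "T"])
    n_var = int(rng.integers(1, 3))
    variants = []
    for pos in sorted(int(p) for p in rng.integers(ps + 1, pe + 1, n_var)):
        ref, alt = rng.choice(bases, 2, replace=False)
        variants.append(Variant(chrom, pos, str(ref), str(alt), Zygosity.HET))
    conservation = ConservationTrack([
        (v.interval, float(np.round(rng.uniform(-1.0, 2.0), 3))) for v in variants
    ])

    p = float(rng.uniform(0.1, 0.9))
    k = int(rng.binomial(config.cohort_size, p))
    cohort_calls = ["C"] * k + ["T"] * (config.cohort_size - k)
    methylation = MethylationProfile(
        [float(r) for r in np.round(rng.uniform(0.05, 0.95, 10), 3)])

    return LocusBundle(
        chrom=chrom, gene=gene, promoter=promoter,
        contacts_coarse=cmap, contacts_fine=cmap,
        tracks=tracks, loops=loops, variants=variants, known_variants=[],
        conservation=conservation,
        cohort_position=variants[0].pos, cohort_calls=cohort_calls,
        methylation=methylation,
        planted_region=planted, decoy_regions=decoys,
    )


def write_bundle(bundle: LocusBundle, outdir) -> Path:
    """Serialize a bundle to standard formats plus a pipeline config YAML.

    Returns the path of the written ``config.yaml``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    write_contacts(bundle.contacts_coarse, outdir / "contacts_coarse.tsv")
    write_contacts(bundle.contacts_fine, outdir / "contacts_fine.tsv")

    track_entries = []
    for idx, track in enumerate(bundle.tracks):
        cell = track.cell_line or "all"
        name = f"{track.track_class.name.lower()}_{cell}_{idx}.bed"
        write_bed(track, outdir / name)
        track_entries.append({"track_class": track.track_class.value,
                              "cell_line": track.cell_line, "path": name})

    loop_entries = []
    for source in LoopSource:
        subset = [lp for lp in bundle.loops if lp.source is source]
        name = f"loops_{source.value}.bedpe"
        write_loops_bedpe(subset, outdir / name)
        res = subset[0].resolution if subset else 5_000
        loop_entries.append({"source": source.value, "resolution": res, "path": name})

    write_vcf(bundle.variants, outdir / "variants.vcf", contigs=[bundle.chrom])
    write_vcf(bundle.known_variants, outdir / "known_variants.vcf",
              contigs=[bundle.chrom])
    write_bedgraph(bundle.conservation, outdir / "conservation.bedgraph")

    with open(outdir / "cohort_calls.tsv", "w") as fh:
        fh.write(f"# position\t{bundle.cohort_position}\n")
        for allele in bundle.cohort_calls:
            fh.write(allele + "\n")
    with open(outdir / "methylation_ratios.tsv", "w") as fh:
        for ratio in bundle.methylation.site_ratios:
            fh.write(f"{ratio}\n")

    gs, ge = bundle.gene.to_printed()
    pstart, pend = bundle.promoter.to_printed()
    config = {
        "chrom": bundle.chrom,
        "gene_start_1based": gs,
        "gene_end_1based": ge,
        "promoter_start_1based": pstart,
        "promoter_end_1based": pend,
        "bin_size_coarse": bundle.contacts_coarse.bin_size,
        "bin_size_fine": bundle.contacts_fine.bin_size,
        "contacts_coarse": "contacts_coarse.tsv",
        "contacts_fine": "contacts_fine.tsv",
        "tracks": track_entries,
        "loops": loop_entries,
        "variants": "variants.vcf",
        "known_variants": "known_variants.vcf",
        "conservation": "conservation.bedgraph",
    }
    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return config_path
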