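# Methods

## The procedure and its assumptions

`remreg` operationalises a six-step screen for remotely acting regulatory
elements. The underlying model is qualitative rather than statistical: a
regulatory element is expected to (i) lie in a genomic fragment that contacts
the gene-containing fragment in Hi-C data, (ii) lie inside the regulatory
domain delimited by CTCF insulator sites flanking the gene, (iii) coincide
with open, factor-bound chromatin (TFBS clusters, DNaseI hypersensitivity)
carrying active histone marks, and (iv) ideally be joined to the gene
promoter by a called chromatin loop. Each step is a deterministic filter;
no significance testing is performed anywhere, because every input is
already a called feature (peaks, enriched regions, loop calls) rather than
raw signal. "Enrichment" therefore means presence/overlap of calls.

Coordinates are 0-based half-open internally (BED convention) and 1-based
inclusive in all reports, with one deliberate exception: loop-anchor
coordinates are reported BEDPE-style (0-based starts), matching how 5-kb
in situ Hi-C anchors are conventionally printed. Strand is parsed and
carried but ignored — the procedure is strand-agnostic. Variants are 1-bp
intervals at their 1-based position (the pipeline targets SNVs; indel spans
are not modelled).

## Steps 1–3: contact binning and ranking

Contacts are consumed pre-binned (4-column TSV: chrom, bin_i, bin_j, count)
at a coarse (default 1 Mb) and optionally a fine (default 100 kb) fragment
size. Bin totals against the gene bin(s) use **raw counts** — no ICE/matrix
balancing, no expected-over-observed model — since only the within-row
ordering matters and richer normalisations would require genome-wide data
the procedure does not otherwise need. For genes spanning several bins, the
ranking sums counts over all gene bins; a per-bin summary
(`interaction_summary`) preserves the per-fragment view. Ties are broken by
ascending bin start for determinism; zero-total bins are never ranked. Only
intra-chromosomal maps are supported — remote elements are sought in *cis*.

The interacting-bin set passed to Step 4 is taken from the **coarse**
ranking: the gene bins plus every bin whose total reaches
`min_interaction_count` (default 100, comfortably above the ~30-contact
background ceiling seen at 100 kb in the worked example and comfortably
below the 663 contacts of the adjacent interacting fragment). The coarse
scale is used deliberately: at 100 kb the gene-fragment union excludes both
flanking CTCF sites of the worked example, while the 1-Mb interacting bins
contain them; the fine map is still read and summarised so weakly
interacting fragments remain visible in the report.

## Step 4: CTCF boundaries

CTCF sites are classified weak/strong at a configurable score threshold
(default 500/1000 — the midpoint of the observed bracket where weak sites
score <445 and a strong site 719; any threshold in (445, 719] yields the
same labels on the worked example). Sites within `ctcf_merge_gap` (default
5 kb) merge into one boundary cluster, so a pair of nearby weak sites acts
as a single upstream boundary. Sites overlapping the gene body are ignored.

Two boundary policies are exposed. The default, `outermost`, bounds the
search region by the *farthest* admissible cluster from the gene on each
side (weak clusters admissible, flagged), reproducing the permissive choice
made in the worked example, where the search was extended into a weakly
interacting fragment to reach the upstream weak cluster. `strict` instead
takes the strong cluster *nearest* the gene and ignores weak sites — the
textbook reading of an insulator boundary. On a side with no admissible
cluster the region falls back to the interacting-bin union edge, recorded
as a sentinel so reports show the fallback. The region never extends past
the interacting-bin union.

## Step 5: evidence integration

Candidates are **anchor-based**: the candidate interval is the span of a
cluster of TFBS and DNase features (union of both classes, gaps ≤
`cluster_gap`, default 200 bp), clipped to the search region — not the span
of the histone-mark domains, which are hundreds of bp to tens of kb wide
with imprecise boundaries. Both sequenced regions of the worked example
coincide with TFBS/DNase-cluster spans, not with their enclosing mark
domains, which motivates this geometry. A cluster is emitted iff it
overlaps at least `min_mark_classes` (default 1) distinct mark classes
among {H3K4me1, H3K27ac, H3K4me3, enhancer calls, active ChromHMM states};
a ChromHMM segment counts only when its state name contains "active".
Classification: H3K4me3 or an active-promoter ChromHMM state ⇒
promoter-like (promoter evidence takes precedence); else any of H3K4me1,
H3K27ac, enhancer or other active ChromHMM evidence ⇒ enhancer-like; else
unclassified. Distances to the gene are signed (negative upstream),
edge-to-edge, reported in kb to one decimal.

One primary cell line can be configured (the worked example uses GM06990,
chosen for Hi-C availability). Features from other cell lines are consulted
only for classes absent from the primary line — mirroring the common
substitution of GM12878 marks where GM06990 data do not exist. The same
rule selects CTCF sites.

## Step 6: loop validation

A candidate is *supported* by a loop source when some loop call has one
anchor overlapping the candidate and the other overlapping the promoter
(anchor order immaterial). The promoter is a configured interval; by
default it is the H3K4me3 interval covering the gene start when one exists,
else gene start ± 2 kb. Separation is measured between candidate and
promoter nearest edges. For Capture Hi-C, candidates with separation ≤
`min_separation` (default 20 kb, the typical promoter-interaction reporting
floor) and no supporting loop are *not assessable* rather than unsupported.
Loop scores are carried through but never thresholded — the supporting
evidence in this procedure is qualitative.

## Variant annotation and cohort utilities

Annotation is pure interval algebra: containing candidates, overlapping
features per track class, a per-base conservation score looked up in a
bedGraph (phyloP semantics: conserved iff score > 0, threshold
configurable), and novelty defined strictly against a user-supplied
known-variant list (chrom, pos, ref, alt) — no online lookups, for offline
reproducibility. Mosaic zygosity is carried as metadata (an explicit
`MOSAIC` INFO flag in VCF), with no variant-allele-fraction modelling.
Cohort tallies use exact rational arithmetic so frequencies sum to 1
identically. The methylation utility averages C-vs-T bisulphite ratios over
a fixed panel (default ten validated CpG sites; any other count is an
error) and reports an integer percentage.

## Synthetic data

`fixtures.paper_locus()` rebuilds the worked-example locus from published
hg18 coordinates, byte-identically across runs. Features that are named in
the published record without printed coordinates (BATF and SPI1 binding
sites, the distal TFBS/DNase anchors, the distal H3K4me3 interval) carry
synthetic spans chosen to be consistent with the printed enclosing regions,
and are marked as such in the source. A lone TFBS decoy with no mark
support is included so the worked example also exercises the filter.

`fixtures.random_locus(SimulationConfig(seed))` generates a random locus
with one planted element — a TFBS cluster spanning exactly the planted
interval, a DNase peak inside it, an H3K27ac mark over it, flanking CTCF
sites and an in situ Hi-C loop to the promoter — plus decoys that each lack
one required evidence class (anchors without marks, marks without anchors).
Contact counts echo the worked example's contrast: gene-bin self-counts of
3371, a planted-bin count of 663, bins across the CTCF span well above the
ranking threshold, background uniform on [0, 30]. A single integer seed
drives every random draw, so bundles are reproducible and the planted
coordinates serve as an exact oracle for end-to-end recovery tests (the
suite checks 100/100 seeds at default configuration).

What the generator does **not** emulate: Hi-C distance-decay, assembly gaps,
overlapping/nested regulatory elements, cell-line batch effects, sequence
content (no FASTA), and realistic TF co-occupancy structure. Passing the
recovery tests therefore demonstrates the pipeline's correctness under its
own model of the data, not peak-calling or mapping robustness on real
assays.

## Numerical and degenerate-input choices

Parse errors name the offending file line (VCF errors carry the reader's
message). An all-zero contact map ranks nothing; an empty evidence track is
valid input yielding zero candidates; an empty feature file is an empty
track, not an error. Track classes form a closed set — unknown class names
are rejected rather than passed through, because evidence integration
depends on the class vocabulary. Candidate evidence lists are sorted by
(class, start, name) and candidates by start, making all outputs invariant
under permutation of inputs. Problem sizes in the test suite (contact maps
up to 50×50 bins, feature sets of a few hundred intervals, 100 simulation
seeds) keep the full suite in the seconds range while covering every
code path; the implementation itself is O(n log n) in features via interval
trees and handles chromosome-scale inputs.

## Known limitations

- Intra-chromosomal only; trans-acting contacts are out of scope.
- No matrix normalisation or loop calling: the pipeline consumes, never
  produces, contact bins and loop calls.
- CTCF orientation (loop-extrusion convergence) is not modelled.
- Candidate geometry inherits the anchor clusters' resolution: a candidate
  is never narrower than its TFBS/DNase cluster span.
- One assembly at a time; no liftOver.
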