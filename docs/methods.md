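# Methods

This note documents the models behind each `longatac` stage, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Coordinates and data model

All internal coordinates are 0-based half-open; VCF positions are
shifted by one at the format boundary only. The atomic unit is the
`Fragment`: one aligned long read of one cell, carrying its interval,
CIGAR events, split-alignment anchors, observed het-SNP alleles and an
optional species label. Each fragment yields exactly two Tn5 insertion
ends; the default end offsets are the standard ATAC +4/−5 convention
(`shift_plus=4`, `shift_minus=5`), clipped so left ≤ right on degenerate
short fragments. The default mapping-quality floor is 30 — haplotype
and SV evidence needs confidently placed long reads; both knobs are
exposed.

## Synthetic experiments (`simulate`)

The generator emulates the data properties the pipeline consumes, not
sequence-level realism. Defaults describe a plate-based long-read
scATAC run:

| parameter | default | meaning |
|---|---|---|
| `fragment_median_bp`, `fragment_sigma` | 4500, 0.35 | log-normal fragment length; medians of real libraries fall in 4–5 kb |
| `reads_per_cell` | 500 | per-cell fragments (real runs reach ~10,000/cell; tests use less for speed) |
| `peak_end_weight` | 0.5 | fraction of reads that anchor one end uniformly inside a peak |
| `het_snp_density` | 1/1500 bp | human-like heterozygosity |
| `base_error` | 0.02 | per-SNP allele miscall probability on a read |
| `asp_skew` | 0.9 | P(maternal) for allele-specific peaks (half planted maternal-, half paternal-skewed) |
| `doublet_fraction`, `species_contam` | 0, 0.02 | merged two-species cells; low-level cross-species label noise |

Reads are drawn per cell from a stream keyed by `(seed, cell_index)`,
so output is byte-deterministic and insensitive to cell order. Each
read is one of: a *co-accessibility molecule* (one end uniform in each
peak of a planted pair), a *peak-anchored read* (one end uniform in a
random peak, the anchor side fair-coin), or *background* (left end
uniform over the genome). Copy-number segments scale both background
position density and peak choice in carrier cells, so depth is
proportional to copy number. Planted deletions/insertions become CIGAR
`D`/`I` events on reads spanning the breakpoint with ≥200 bp margin;
translocation reads truncate at the junction and carry a split anchor
to the partner locus, mirroring how an aligner represents them.
`sv_noise_rate` adds random ≥50 bp indels to single reads to exercise
the distinct-cell filter.

Since a peak-anchored read places only one of its two ends inside a
peak, the expected FRIP is approximately `peak_end_weight/2` plus the
peak fraction of the genome — about 0.26 at defaults.

What is **not** emulated: basecalling errors beyond SNP allele flips,
mappability and GC bias, chimeric artifacts, duplicate reads, nucleosome
periodicity, and cell-to-cell depth variation beyond CNV scaling.
Passing recovery tests therefore demonstrates the estimators' logic and
calibration under the stated generative model, not robustness to every
artifact of real libraries.

`downsample_pseudobulk` partitions a pooled read set into synthetic
cells without replacement (the throughput-titration design; 10,000
reads per cell is a realistic upper bound).

## QC

TSS enrichment aggregates strand-oriented insertion-end counts in
10 bp bins over ±2 kb; the score is the center bin divided by the mean
of the outermost 10% of bins on each side (ENCODE-style background).
A flat library scores ~1; an empty flank yields +inf, no ends at all
NaN with a warning. Footprint profiles are the unstranded analogue.
FRIP is `#ends inside any merged peak / #ends`. A cell is a doublet
when its minor-species fraction exceeds `min_minor_fraction`
(default 0.1 — far above the ~2% contamination floor, far below the
~50% of a true doublet).

## Peak calling

Sliding windows (500 bp, step 100 bp) are scored by the Poisson upper
tail `P(X ≥ k; λ)` with `λ = max(genome-wide rate, local rate over
10 kb) × window` — the local-maximum background makes the caller robust
to broad enrichment. Windows need `k ≥ 5` ends and `p ≤ 1e−5`;
overlapping or ≤100 bp-separated significant windows merge, keeping the
best `−log10 p` as score. The caller is deterministic and its output
disjoint and sorted; relaxing `p_threshold` can only grow peaks. On a
uniform background the expected false-positive window count is below
`p_threshold × #windows` (the max-background makes it conservative; the
calibration experiment bounds it at 3× that).

Peak-set comparison counts ≥1 bp intersections asymmetrically per set
(the two assays' peak widths differ, so the two fractions differ);
benchmark precision/recall use the same rule against a reference
element set. Category annotation assigns each peak its first
overlapping category in the priority order PLS > pELS > dELS >
CTCF-only > DNase-H3K4me3.

## Allele-specific accessibility

Reads are haplotyped by majority vote over the phased het SNPs they
cover: assign hap1/hap2 iff the margin is ≥1 and the winning fraction
is ≥2/3, else ambiguous. Crucially the SNPs may lie anywhere on the
read — a peak with no internal het SNP is testable through flanking
SNPs within a read length, which is the long-read-specific capability
the recovery tests pin down (ASPs planted SNP-free are recovered at the
same power as SNP-containing ones).

A read supports a peak when either insertion end falls inside it (the
FRIP convention; a both-ends-in-peak read counts once). Peaks with ≥10
haplotyped reads get a two-sided exact binomial test against 0.5;
Benjamini–Hochberg runs across all tested peaks jointly (not per
chromosome). The 0.5 null reflects the symmetric maternal/paternal
design; an empirical null proportion can be passed where reference bias
is a concern. `min_total=10` merely excludes degenerate tests — the
binomial test is exact at any n.

Phasing builds a graph over het SNPs with edge weight
`#cis − #trans` from reads covering consecutive SNP pairs; zero-weight
edges are dropped (balanced evidence phases nothing). Each component is
oriented by propagation along its maximum-|weight| spanning tree —
deterministic and near-optimal at ATAC-like coverage, in place of exact
MEC optimization. The switch error rate compares consecutive
commonly-phased SNP pairs within one called block against truth; it is
invariant to whole-block flips by construction.

## Structural variants

Candidates: CIGAR `I`/`D` ≥ `min_sv_len` (50 bp) and cross-chromosome
split anchors (the primary's terminus is the breakpoint). Clustering is
single-linkage: INS/DEL link within 500 bp breakpoint distance and
≥0.7 length ratio, TRA within 500 bp at both breakpoints; call position
and length are member medians. Calls require ≥5 **distinct** supporting
cells — reads of a single cell, however many, cannot call an event,
which is what suppresses per-cell artifacts. Benchmarking matches
greedily one-to-one by breakpoint distance (1000 bp tolerance — looser
than clustering, as is conventional for long-read SV comparison), per
type, across a `min_cells` sweep; recall is non-increasing in the
threshold on any fixed input. Somatic filtering keeps case calls with
no control match under the same rule. Inversions and duplications are
outside the candidate grammar.

## Copy number

Fragments are binned by midpoint (a long fragment spanning a boundary
counts once), default 1 Mb bins — large-scale events only, no
segmentation. Depth is `raw / cell_total / reference`, rescaled so each
cell's autosomal median equals the assumed ploidy (2 by default;
1 for haploid lines), then rounded half-away-from-zero to integer CN
with the continuous depth always reported alongside.

The default reference is **width-proportional** ("uniform"): it yields
absolute copy number and recovers events shared by every cell — the
diagnostic example being a male-derived line whose X sits at half the
autosomal depth, which a median-across-cells reference would silently
absorb. The `"median"` reference remains available: it cancels shared
coverage biases (peak enrichment, mappability) and is the right choice
for subclone detection relative to the cell majority; an external
per-bin array (e.g. from a diploid control) combines both virtues. No
GC/mappability correction is built in — synthetic data has none; a
user-supplied covariate can be folded into the reference.

## Co-accessibility

Candidate pairs are same-chromosome, non-overlapping peaks whose center
distance is at most 2× the local median read length (median fragment
length in a 100 kb window, falling back to the global median below 20
local fragments) — molecules cannot bridge farther, so farther pairs
are out of scope by construction. For a pair (A, B), the observed count
is fragments with the left end strictly in A and the right end strictly
in B (`pad=0`; one orientation only, so no molecule counts twice); the
expectation sums, over A-anchored fragments, the empirical
length-distribution probability of reaching into B. The observed count
is tested by a Poisson upper tail and BH-corrected across candidates.
This spanning-molecule Poisson model is this package's explicit
formalization of the idea that co-accessibility alters the length
distribution of peak-supporting reads.

Calibration on the simulator's independent-ends null runs at a ~7–8%
discovery fraction at q ≤ 0.05 (slightly above nominal: a read anchored
by its right end in B whose left end happens to land in A is
conditioned on spanning, which the length-CDF expectation does not
know), within the 10% band the validation asserts. On planted pairs the
supporting-read length necessarily tracks the peak distance (Spearman
ρ ≈ 1 across discovered pairs), since a spanning molecule is at least
as long as the gap it bridges.

## Validation problem sizes

The recovery experiments in `longatac.validation` (also driven by
`scripts/acceptance.py`) use: ASP — 10 replicates of 1000 peaks on
2×12.5 Mb, 2% ASPs at skew 0.9, ~50 haplotyped reads/peak; flanking-SNP
ASP — 500 peaks, 40 ASPs, half stripped of internal SNPs; phasing —
4 chromosomes × 100 SNPs at 20× coverage, 5% base error; SV — 100
planted events on 2×10 Mb, 100 cells, half carriers, ~160k reads;
CNV — 12 cells at ~200 fragments per 500 kb bin; co-accessibility —
3 replicate pairs of null/planted runs with 50 planted pairs at
2–15 kb; peak-caller null — 40k uniform ends over 10 Mb. These sizes
keep each experiment in the seconds-to-tens-of-seconds range while
leaving the asserted margins wide.

## Known limitations

* The generator's independence assumptions (flat background, no
  GC/mappability structure, error-free read placement) make the
  recovery results a test of estimator logic and calibration, not of
  robustness to alignment artifacts.
* ASP counts treat reads as independent; true per-cell correlation
  (two reads of one allele in one cell) would mildly inflate
  significance and is not modeled.
* SV genotyping is presence/absence per cell; no breakpoint refinement
  or local re-assembly.
* CNV profiles have bin-level resolution and no segmentation; subclone
  *discovery* (grouping cells) is left to the caller — groups are an
  input to `aggregate_profiles`.
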