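# longatac

Chromatin accessibility **and** genetic variation from long-read
single-cell ATAC fragments.

Plate-based single-cell ATAC-seq on a long-read (nanopore-class)
platform produces per-cell fragments with 4–5 kb median length. The two
ends of each fragment are Tn5 insertion sites — ordinary accessibility
evidence — but the long molecule between them additionally carries
heterozygous-SNP alleles, large CIGAR insertions/deletions and split
alignments. `longatac` exploits both layers at once:

* **QC** — TSS enrichment, FRIP (fraction of read ends in peaks),
  fragment counts, footprint profiles, species-mixing doublet calls.
* **Peaks** — a sliding-window caller on insertion-end density with a
  local Poisson background, peak-set overlap/benchmark/annotation, and
  sparse cell × peak / cell × gene count matrices.
* **Allele-specific peaks (ASPs)** — reads are haplotyped from phased
  het SNPs they cover, *including SNPs flanking the peak*: a peak with
  no internal SNP is still testable because a 4–5 kb read anchored in
  the peak reaches het sites kilobases away. Per peak, maternal vs
  paternal read counts get a two-sided exact binomial test against
  0.5 with Benjamini–Hochberg FDR control.
* **Phasing** — unphased het SNPs are phased from allele co-occurrence
  on single reads (max-weight spanning tree over the cis−trans evidence
  graph), scored by the switch error rate.
* **SVs** — insertions/deletions from ≥50 bp CIGAR events,
  translocations from cross-chromosome split alignments, clustered
  across cells by single-linkage; a call requires support from
  **distinct cells** (default ≥5), so one noisy cell cannot create an
  event. Somatic calls are case-minus-control.
* **CNVs** — per-cell integer copy number from midpoint-binned fragment
  depth, library-size- and reference-normalized, autosomal median
  rescaled to ploidy.
* **Co-accessibility** — two neighboring peaks are co-accessible when
  single molecules repeatedly place one Tn5 end in each peak. Candidate
  pairs are capped at 2× the local median read length; the observed
  spanning-molecule count is tested against a Poisson expectation from
  the empirical fragment-length distribution.
* **Simulator** — a synthetic-data generator that plants peaks, ASPs,
  haplotypes, SVs, CNVs, co-accessible pairs and doublets, and emits a
  complete truth ledger; every stage above is validated by recovering
  what it planted.

## The core statistics

For a peak with `n_m` maternal and `n_p` paternal haplotyped reads, the
ASP test is the exact binomial `p = P(|X − n/2| ≥ |n_m − n/2|)`,
`X ~ Bin(n, 0.5)`, `n = n_m + n_p ≥ 10`, BH-corrected at FDR 0.05.

For a peak pair (A, B) at center distance `d ≤ 2·median_local(len)`,
with `F` the empirical fragment-length CDF, the expected number of
spanning molecules is

```
λ = Σ over fragments with left end e ∈ A of [F(B.end − e) − F(B.start − e)]
```

and the observed count of molecules with one end in each peak is tested
with the Poisson upper tail `P(X ≥ obs; λ)`, BH-corrected across pairs.

An SV cluster is called when `|{distinct supporting cells}| ≥ k`
(default `k = 5`); precision/recall are reported across a sweep of `k`.

## Worked example

One command simulates a small experiment (80 cells, three chromosomes,
120 peaks, planted ASPs/SVs/CNVs/co-accessible pairs) and runs every
stage against the planted truth:

```
$ longatac demo --seed 1 --outdir demo_out
[longatac 0.1.0] demo outdir=demo_out seed=1
check asp_fdr_controlled: PASS
check asp_power: PASS
check cnv_recovered: PASS
check coaccess_recovered: PASS
check peaks_recovered: PASS
check qc_frip_reflects_peak_weight: PASS
check sv_recovered: PASS
all recovery checks passed; report -> demo_out/report.json
```

`report.json` then holds the measured metrics:

```json
{
 "asp_power": 1.0,
 "asp_realized_fdr": 0.0,
 "cnv_consensus_accuracy": 1.0,
 "coaccess_power": 1.0,
 "frip": 0.258,
 "peak_precision": 0.984,
 "peak_recall": 1.0,
 "sv_recall_min": 1.0
}
```

Reading the numbers: every planted peak was re-called from insertion-end
density (`peak_recall` 1.0); all planted allele-specific peaks were
recovered with no false discovery; the FRIP of ~0.26 matches the
simulated design, where half of all reads anchor one of their two ends
in a peak; planted deletions, insertions and the translocation were all
called from ≥3 distinct cells; the chr2 subclonal gain and the X
chromosome at copy number 1 were recovered exactly in the group
consensus; and all planted co-accessible pairs were found by the
spanning-molecule test.

Individual stages run as subcommands on a fragment table (or SAM/BAM
with a cell tag), BED peaks and a VCF of het SNPs:

```
longatac simulate --seed 1 --outdir sim/
longatac callpeaks --fragments sim/fragments.tsv --chrom-sizes sim/chrom.sizes --out peaks.bed
longatac qc        --fragments sim/fragments.tsv --peaks peaks.bed --out qc.tsv
longatac asp       --fragments sim/fragments.tsv --vcf sim/hets.vcf --peaks peaks.bed --out asp.tsv
longatac phase     --fragments sim/fragments.tsv --vcf sim/hets.vcf --out phased.vcf
longatac sv        --fragments sim/fragments.tsv --out svs.tsv
longatac cnv       --fragments sim/fragments.tsv --chrom-sizes sim/chrom.sizes --out cnv.tsv
longatac coaccess  --fragments sim/fragments.tsv --peaks peaks.bed --out pairs.tsv
```

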