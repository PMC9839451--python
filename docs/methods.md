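# Methods

## Problem and model

Spurious (cryptic) transcription is initiation inside a gene body rather
than at the canonical promoter. It is normally suppressed by
co-transcriptional chromatin marks (H3K36me3, and in smooth-muscle cells
the TET3-dependent 5hmC pathway that recruits SETD2); when suppression
fails, knockout (KO) cells accumulate intragenic initiation events.
`spurcatch` detects affected genes by requiring three independent pieces
of evidence to agree:

1. **Exon-ratio (RNA-seq).** For a gene with exons e₁…eₙ in
   transcription order, let RPKMᵢ be the length- and depth-normalised
   read density of exon i. The statistic is

   r = log₂[(mean(RPKM₂…RPKMₙ₋₁) + ε) / (RPKM₁ + ε)],  ε = 0.1 RPKM.

   Canonical transcription gives r ≈ 0; transcripts initiating
   downstream of exon 1 push r up. Genes with more than four exons and
   replicate-mean r > 1 in KO pass the filter. The last exon is excluded
   from "intermediate" by default because 3′ coverage bias makes it
   unrepresentative; a switch includes it. Replicates are averaged on
   the log₂ scale (symmetry of up/down deviations).

2. **KO-specific intragenic CTSSs (CAGE).** CAGE reads are collapsed to
   single-base tag start sites (5′ base: interval start on +, end−1 on
   −). A site is a called CTSS when its raw tag count strictly exceeds
   8 (the genome-wide average per-base count at annotated TSSs). The
   intragenic signal of a gene is the sense-strand tag/TPM sum inside
   the transcript span with every base of exon 1 removed (introns
   included — initiation is a genomic event). A gene passes when (a)
   some intragenic sense position exceeds the tag threshold in a KO
   sample while staying at or below it in every control, and (b) the
   replicate-mean KO TPM sum is ≥ 1.3× the control mean with a +1 TPM
   pseudocount on both sides. The raw-count threshold and the
   TPM-normalised fold reconcile the two roles of the tag cutoff: 8 is
   a raw-count calibration, while the fold compares libraries of
   different depth.

3. **Pol II pSer5 intragenic entry (ChIP).** Treatment and input tracks
   are scaled to per-million units, chromosomes are partitioned into
   50-nt windows anchored at coordinate 0, and the input window sum is
   subtracted from the treatment window sum with negative windows set
   to zero (the final partial window is averaged over its true length).
   Gene-body scores use mean0 semantics (uncovered bases count as 0)
   over the exon2→TES body, and the per-gene statistic is
   log₂((KO + 1)/(Ctrl + 1)). "Enhanced intragenic entry" is the
   weakest reading: log₂ fold change strictly above 0 (configurable).

The final call is the conjunction of the three filters; the package also
reports the seven exclusive Venn regions and the fraction of the CTSS
set passing everything.

**Gene body.** The default body definition is exon 2 through the TES,
treating exon 1 as the canonical-initiation zone; the full TSS→TES span
is retained for metagene display. Whether introns or exon 1 belong to
the "body" of a metagene is a presentation choice, so both definitions
are exposed rather than guessed.

**Supporting machinery.** Median-of-ratios size factors follow DESeq2's
arithmetic exactly (median of log ratios over regions with all-positive
geometric means, exponentiated, unscaled). Quartile (a–d, descending)
and expression-quintile grouping sort descending with lexicographic
gene-id tie-breaks; uneven remainders go to the top groups, so group
sizes differ by at most one. Metagene profiles rescale each body to 100
bins and use fixed 50-bp flank bins over ±2,000 bp; flank widths and bin
counts are declared defaults, not inferred values. qPCR arithmetic: ΔΔCt
relative expression (ΔCt = Ct_ref − Ct_target; fold = 2^ΔΔCt) and hMeDIP
percent recovery 2^[(Ct(10% input) − 3.32) − Ct(IP)]·100 with the
dilution constant stored as the printed literal 3.32 (a high-precision
mode substitutes log₂10 ≈ 3.3219).

## Motif-window enrichment

Windows of ±50 nt are cut around each KO-specific CTSS, sense-oriented
(minus-strand windows reverse-complemented so index 50 is the initiating
base). Background windows are drawn uniformly from the intragenic
sense-strand space of the same genes (exon 1 excluded, foreground
positions excluded), deterministically per seed. Enrichment of CpG
dinucleotides (and of IUPAC consensus motifs) is the ratio of mean
per-window counts (or hit rates); significance is a two-sided
label-permutation test with the +1 correction, so p ≥ 1/(n_perm+1).
Permutation replaces de novo motif discovery, which is out of scope;
targeted consensus scanning against a decoy panel plays its role on
synthetic data.

## Synthetic data generator

The generator emulates the statistical structure of the real multi-omics
design with planted, recoverable truth:

- **Geometry.** 2,000 genes by default, 5–12 exons of 200–1,000 bp,
  introns 200–2,000 bp, 50 genes per chromosome separated by 2-kb gaps.
  Sequence is i.i.d. with base probabilities (0.4, 0.1, 0.1, 0.4), giving
  a CpG dinucleotide frequency of 0.01 (vertebrate-like depletion).
- **Expression.** Latent per-gene expression is lognormal (ln-mean 3,
  ln-sd 1); quintile tiers (1 lowest … 5 highest) drive the body marks.
- **RNA-seq.** Exon counts are negative binomial with dispersion 0.1
  around expression × exon kb × depth, where depth normalises the
  expected control library to 2×10⁶ reads. In KO samples, spurious genes
  (10% of genes) have exons 2…n−1 multiplied by 4.
- **CAGE.** Canonical tags are Poisson around each TSS (±2 bp jitter,
  rate 1 tag per expression unit, sense strand); KO samples add
  Poisson(30) tags at each of 1–3 planted cryptic sites per spurious
  gene; a uniform noise floor of 10⁻⁴ single tags per base per strand
  stays far below the tag threshold.
- **ChIP.** pSer5 = Gaussian TSS peak (amplitude 0.5×expression, sd 100)
  plus a 0.02×expression body plateau; KO spurious genes gain +2
  counts/base over the body and Gaussian cryptic peaks (amplitude 5,
  sd 50). H3K36me3 and 5hmC are body-wide at 0.4 and 0.3 counts/base per
  expression tier, scaled ×0.3 over spurious bodies in KO. Input is
  uniform Poisson(1). All tracks are integer Poisson draws.
- **Truth.** Cryptic sites sit strictly inside the exon2→TES body with a
  60-bp margin and ≥200-bp spacing, and the consensus motif (CCGCCC) is
  written into the genome at each site on the sense strand.

Everything is deterministic for a fixed seed (independent substreams per
generator), and `write_dataset` stamps a configuration digest into every
output file.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: mappability and alignment artifacts, GC and
3′ coverage bias, isoform structure and alternative promoters, CAGE tag
clusters wider than one jittered base, antisense transcription beyond a
uniform noise floor, chromatin-state autocorrelation in input, batch
effects, and biological replicate variability beyond counting noise.
Benchmark precision/recall on this generator measures the pipeline's
arithmetic and thresholds under the declared noise model, not
performance on real libraries.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open throughout; GTF converts at the
  boundary. The TSS of a minus-strand gene is the highest coordinate of
  exon 1.
- Pseudocounts: 0.1 RPKM (exon ratio), 1 TPM (CTSS fold), 1.0 (track
  log ratios); all configurable.
- Thresholds are strict (> 8 tags, > 1 log₂ ratio, > 0 Pol II fold,
  ≥ 1.3 CTSS fold) exactly as stated by their definitions.
- Single-exon genes raise explicit "no gene body"/"no intragenic region"
  signals instead of returning numbers; genes shorter than the body bin
  count are skipped from metagenes with a warning; unknown chromosomes
  warn and score zero rather than fail.
- Size-factor estimation errors out when no region is positive in all
  samples; empty tracks cannot be depth-normalised.
- Benchmark problem sizes: the shipped tests exercise the full pipeline
  at the default 2,000-gene configuration and module behaviour at
  150-gene scale; both were chosen as the smallest sizes at which tier
  statistics and recovery rates are stable.

## Known limitations

- The intragenic CTSS call compares positions across samples without
  library-size adjustment at the position level (only the gene-level
  fold is normalised); strongly unbalanced libraries would bias the
  specificity condition.
- The Pol II "enhanced entry" floor of 0 is the weakest defensible
  reading; real analyses may want a positive margin.
- bedGraph is the only track interchange format (BigWig is out of
  scope), and dense per-base arrays bound the practical genome size to
  tens of megabases per track.
- The permutation test assumes exchangeable windows under the null;
  windows overlapping each other (cryptic sites closer than 100 bp)
  would violate independence, which the generator's 200-bp site spacing
  avoids.
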