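# spurcatch

Detection of **spurious (cryptic) intragenic transcription** — initiation
inside gene bodies rather than at canonical promoters — from three
complementary genomics readouts, integrated into a single per-gene call:

- **RNA-seq exon quantifications** — the exon-ratio statistic
  `r = log2[(mean RPKM of exons 2..n−1 + ε) / (RPKM of exon 1 + ε)]`.
  Canonical transcription gives r ≈ 0; transcripts initiating downstream
  of exon 1 push r up. Genes with > 4 exons and replicate-mean r > 1 in
  the knockout (KO) pass.
- **CAGE transcription start-site tags** — reads collapsed to single-base
  CTSSs; a gene passes when it has a sense-strand intragenic position
  (exon 1 excluded, introns included) with > 8 raw tags in KO but not in
  any control, and ≥ 1.3-fold higher intragenic tags-per-million than
  control.
- **Pol II pSer5 ChIP** — depth-normalised tracks are background-corrected
  by 50-nt windowed input subtraction with zero clamping; a gene passes
  when its gene-body (exon 2 → TES) log2(KO/Ctrl) score exceeds 0.

The package is aimed at epigenomics/regulatory-genomics analysts studying
chromatin-mediated suppression of intragenic initiation (H3K36me3, 5hmC /
TET3 systems). It also ships CpG/motif-window enrichment around cryptic
start sites (permutation-tested against matched intragenic background),
metagene profiling, DESeq2-style median-of-ratios size factors,
quartile/quintile grouping, ΔΔCt and hMeDIP percent-recovery arithmetic,
and a fully deterministic synthetic-data generator with planted ground
truth for benchmarking the whole pipeline.

## Worked example

Simulate 200 genes (10% spurious, 4-fold intermediate-exon gain in KO,
Poisson(30) cryptic CAGE tags per planted site) and run the integrated
detection:

```python
from spurcatch import SimConfig, run_pipeline
from spurcatch.integrate_motif import (
    cpg_enrichment, extract_ctss_windows, sample_background_windows)

res = run_pipeline(SimConfig(n_genes=200), keep_sim=True)
print(f"final calls : {len(res.final_genes)} of {res.n_genes} genes")
print(f"venn        : {res.venn}")
print(f"precision   : {res.precision:.3f}   recall: {res.recall:.3f}")

fg = extract_ctss_windows(res.sim.sequences, res.ko_specific_positions, flank=50)
called = [g for g in res.sim.genes if g.gene_id in res.final_genes]
bg = sample_background_windows(called, res.sim.sequences, 2 * len(fg),
                               seed=17, excluded=set(res.ko_specific_positions))
cpg = cpg_enrichment(fg, bg, n_perm=999, seed=17)
print(f"CpG fold    : {cpg.fold:.2f}   permutation p: {cpg.p_value:.4g}")
```

prints

```
final calls : 20 of 200 genes
venn        : {'exon_only': 0, 'ctss_only': 0, 'polii_only': 0, 'exon_ctss': 0,
               'exon_polii': 0, 'ctss_polii': 0, 'all_three': 20}
precision   : 1.000   recall: 1.000
CpG fold    : 2.05   permutation p: 0.001
```

All 20 planted spurious genes pass all three filters (the seven numbers
are the exclusive Venn regions of the three evidence sets), no clean gene
is called, and the ±50-nt windows around the recovered cryptic start
sites carry twice the CpG density of matched intragenic background — the
planted CpG-containing consensus shows up exactly where initiation was
planted.

The same stages are available from the shell:

```sh
spurcatch simulate --out data --seed 17
spurcatch exonratio --counts data/exon_counts.tsv --samples data/samples.tsv
spurcatch chipcorrect --treatment data/pSer5_KO.bedgraph --input data/input_KO.bedgraph
spurcatch qpcr --mode hmedip --input ct_values.tsv
```

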