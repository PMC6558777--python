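# startseq

Analysis of **Start-seq** data — sequencing of short 5′-capped RNAs (TSS-RNAs)
produced by promoter-proximally paused RNA polymerase II. Each read carries
dual information: its 5′ end marks the nucleotide at which Pol II initiated
transcription, and its 3′ end marks where Pol II paused. From stranded aligned
reads (BED6), a gene annotation (GTF/BED), a genome (FASTA) and an expression
table (TSV), the package provides:

- **TSS reannotation** at base-pair resolution: per-gene sense-strand 5′-end
  peak calling in a ±500 bp window, a 10-read noise filter applied per
  replicate, and a distance filter that keeps a gene only when its peak offset
  lies within one SD of the normal distribution fitted to all peak offsets.
- **Antisense transcription**: divergent (opposite strand, ≤500 bp upstream,
  pointing away from the gene) and convergent (opposite strand, ≤500 bp
  downstream, pointing into the promoter) TSS calls, quantified by ±50 nt
  counts around each called peak, with replicate Spearman correlation matrices.
- **Pol II pausing**: the pausing index `PI = (sense 5′-end count in TSS ± 500 bp) / FPKM`,
  3′-end metaprofiles around reannotated TSSs (pause sites peak ~+35 nt),
  RNA length as a function of each RNA's own initiation position, and an
  initiation-class analysis that discriminates distance-anchored from
  sequence-anchored pausing by comparing 3′-end positions of RNAs initiating
  in the [−10,−5] versus [+5,+40] bands around the main TSS.
- **Initiator (Inr) motif analysis**: strand-aware sequence contexts, position
  frequency matrices and per-position information content
  `IC(o) = 2 + Σ_b f_b(o) log₂ f_b(o)` bits, plus the G/C preference at RNA 3′ ends.
- **Non-genic initiation elements**: strand-specific peak calling (or an
  external peak BED), exclusion of peaks within ±3 kb of any known TSS, and
  merging of peak chains (consecutive summits ≤3 kb apart, at least one
  adjacent opposite-strand pair) into bidirectional regions — the Start-seq
  signature of enhancer-like elements. A multi-exon filter separates credible
  novel intergenic transcripts from assembly artifacts.
- **A synthetic study generator** (`startseq.synth`) that plants a genome,
  misannotated TSSs, stranded reads, antisense initiation, bidirectional
  elements, an Inr PWM and pausing indices — with every planted value recorded
  in truth tables — so the whole pipeline is testable end to end without
  external data.

All coordinates are 0-based half-open internally; GTF input is converted on
load. Windows written "±N" include both boundary offsets.

## Worked example

Simulate a study, then run every stage:

```sh
startseq simulate --seed 11 --outdir demo --n-genes 100 --n-elements 10
startseq run \
  --reads demo/reads_rep1.bed --reads demo/reads_rep2.bed \
  --annotation demo/genes.gtf --genome demo/genome.fa \
  --expression demo/fpkm.tsv --outdir demo_out
```

which prints (abridged):

```
  n_genes_above_noise: 100
  n_genes_pass: 72
  n_reannotated_gt_5: 51
  offset_fits: [{'mean': -1.82, 'sd': 18.38, 'n': 100}, ...]
  n_divergent: 56
  n_convergent: 24
  three_prime_peak_offset: 32
  inr_ic_center_reannotated: 1.34
  inr_ic_center_annotated: 0.05
  n_bidirectional_regions: 10
```

Reading: all 100 genes clear the 10-read noise threshold; 72 fall within one
fitted SD (±18.4 nt around −1.8) of the annotated TSS and are reannotated, 51
of them by more than 5 bp (the generator planted annotation errors with SD
20 nt). 56 genes get a divergent and 24 a convergent antisense call. TSS-RNA
3′ ends peak ~+32 nt downstream of the reannotated TSSs. The information
content at the reannotated TSSs (1.34 bits) far exceeds that at the original
misannotated positions (0.05 bits) — the planted initiator motif is only
visible once the TSSs are corrected. All 10 planted bidirectional elements are
recovered. Full per-gene tables (TSV), per-strand 5′/3′ bedGraph tracks, BED
files and `summary.json` are written to `demo_out/`.

Every stage is also callable as a library function (`startseq.tss.reannotate_tss`,
`startseq.antisense.call_antisense_tss`, `startseq.pausing.pausing_index`, ...)
or as a single-stage subcommand (`startseq tss`, `startseq pausing`, ...).

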