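# hepadim

Analysis pipeline for quantifying the **loss of liver-specific and sexually
dimorphic hepatic gene expression** under persistent aryl hydrocarbon
receptor (AhR) activation — the transcriptomic signature of a functionally
"de-differentiated" liver produced by dioxin (TCDD) exposure in mice.

It is aimed at toxicogenomics and liver-biology groups who have bulk RNA-seq
contrasts (per-sex treated-vs-vehicle, male-vs-female vehicle), AhR ChIP-seq
peaks and a multi-tissue expression compendium, and want the full chain from
raw statistics to biological calls as reusable, tested code.

## What it computes

- **Tissue specificity** (`hepadim.specificity`). For gene *g* and target
  tissue *T*: ΔSignal(g) = s(g, T) − max over other tissues t of s(g, t);
  genes with ΔSignal ≥ 5,000 signal units are called tissue-specific
  (absolute difference, not fold change, so only highly expressed genes
  qualify).
- **Sexual dimorphism / differential expression** (`hepadim.dimorphism`).
  Counts → arcsinh variance-stabilizing transform on median-of-ratios
  normalized counts → median-centering → per-gene moderated *t* → a
  two-component empirical-Bayes scale mixture fitted by EM, giving the
  posterior P1(*t*) that a gene is differential. Calls use
  |fold| ≥ 2.0 & P1(*t*) ≥ 0.8 (dimorphism) or |fold| ≥ 1.5 & P1(*t*) ≥ 0.8
  (differential expression), thresholds inclusive.
- **Pre-ranked enrichment** (`hepadim.enrichment`). Genes ranked from most
  induced to most repressed; the running sum gains 1/N_h at set members and
  loses 1/(N−N_h) elsewhere; ES is the extremum of the walk, with a gene-set
  permutation p-value.
- **Genomic neighborhoods** (`hepadim.neighborhood`). A per-chromosome
  running sum of DE log2 fold-changes in TSS order; sustained same-sign runs
  (≥ 3 DE genes, |Δscore| ≥ 4, gap tolerance 2) mark putatively co-regulated
  blocks such as the chromosome-4 *Mup* cluster.
- **Regulatory context** (`hepadim.regulatory`). Dioxin response element
  (5'-GCGTG-3' core) discovery by conservation-weighted matrix similarity
  score (consensus = 1.0 exactly; functional cutoff MSS ≥ 0.85), AhR
  peak-to-gene assignment (FDR ≤ 0.05; gene body + 10 kb TSS-side flank),
  male/female/both/neither gene partitions and pDRE-in-peak co-occurrence.
- **Convergence** (`hepadim.convergence`). For each baseline sex-biased gene,
  the dimorphism index d = log2(male/female) is updated additively with the
  per-sex responses; genes are classified as `lost_dimorphism`,
  `feminized_male`, `masculinized_female`, `reinforced` or `unchanged`.
- **Synthetic data** (`hepadim.simulate`). Generates every input with planted
  ground truth (liver-specific genes, sex-biased genes, a co-repressed gene
  block, consensus DREs under ChIP peaks), so the whole pipeline is testable
  offline.

## Worked example

Simulate a bundle and run two stages:

```sh
hepadim simulate --outdir data --seed 3 --n-genes 400 --n-tissues 8 \
    --n-specific 40 --n-chrom 1 --genes-per-chrom 60
hepadim specificity --atlas data/atlas.tsv --tissue liver \
    --out-scores out/scores.tsv --out-geneset out/liver.txt
# cluster.txt = the planted co-repressed block from data/truth.json
hepadim gsea --ranks data/fold_changes.tsv --contrast tcdd_30ug \
    --geneset out/cluster.txt --n-perm 999 --seed 0 --out out/gsea.tsv
hepadim neighborhood --genes data/genes.bed --fc data/fold_changes.tsv \
    --contrast tcdd_30ug --out-track out/track.tsv --out-segments out/segments.bed
```

prints

```
40 liver-specific genes at DeltaSignal >= 5000
ES=-1.0000 p=0.001 (Nh=8)
1 segments
```

with `out/segments.bed` containing

```
chr1	510000	650001	repressed	32.0	8
```

The 40 planted liver-specific genes are recovered exactly by the ΔSignal
rule. The planted 8-gene repressed block sits entirely at the repressed end
of the treatment ranking, so its enrichment score reaches the extreme
ES = −1.0 (permutation p = 0.001, the add-one floor at 999 permutations),
and the neighborhood scan localizes the same block as one repressed segment
of magnitude 32 log2 units (8 genes × −4 each) with exact boundaries.

The same stages are available as library calls (`simulate_atlas`,
`delta_signal`, `dimorphism_analysis`, `enrichment_score`,
`running_fold_change`, `mss_scan`, `classify_convergence`, ...); the CLI is
a thin wrapper.

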