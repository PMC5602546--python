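# Methods

This note documents the models, parameter choices and numerical conventions
behind `hepadim`, and what the synthetic-data tests do and do not establish
about real data.

## Coordinates and formats

All intervals are 0-based half-open (BED convention) internally; GFF3 input
(1-based closed) is converted at the reader boundary, and the TSS of a gene
is its `start` on the plus strand and `end − 1` on the minus strand.
Tabular exchange is tab-separated UTF-8 with `#` comments. Containers
validate their invariants on construction (unique identifiers, nonnegative
signal/counts, P1(t) and FDR within [0,1], nonempty intervals) and readers
fail loudly, naming the offending row, rather than repairing input.

## Tissue specificity

ΔSignal is the target-tissue signal minus the per-gene maximum over all
other tissues; the call threshold (default 5,000 signal units) is inclusive.
Ties with the best other tissue give ΔSignal ≤ 0 and exclusion — no special
casing. The rule operates on an absolute difference deliberately: a fold
change would admit low-expression genes whose ratios are large but whose
absolute output is negligible. The atlas must already be collapsed to one
row per gene; probe-to-gene collapse policy is upstream of this package.

## Variance stabilization, normalization, P1(t)

- **Size factors** are median-of-ratios against the per-gene geometric mean
  over samples (genes with any zero excluded from the reference; library
  totals as fallback). Rescaling one sample's counts by λ scales its factor
  by λ relative to every other sample's — the invariant tested — though all
  normalized values pick up a common λ^(1/n) through the pseudo-reference,
  which cancels in between-group differences.
- **VST** is arcsinh(count/size_factor): exactly 0 at count 0, ~ln(2x) for
  large counts, so group differences divided by ln 2 read as log2
  fold-changes. On negative-binomial data at dispersion 0.05 the bin-wise
  log-sd vs log-mean slope after transform is near 0 (tested within
  ±0.25).
- **Normalization** median-centers each sample against the per-gene median
  pseudo-reference; pure per-sample offsets are removed exactly. This is a
  documented, swappable stand-in for location alignment — deliberately the
  simplest semi-parametric-style location adjustment.
- **P1(t)**: per gene, a moderated t is formed with pooled group variance
  shrunk toward the global mean variance with ν₀ = 4 prior pseudo-samples.
  The t values are modeled as a two-component zero-mean Gaussian scale
  mixture: a null component (σ₀) and a wider differential component
  (σ₁ ≥ 2σ₀), fitted by EM on π₁, σ₀ and the scale ratio; P1(t) is the
  posterior of the wide component. Zero-mean components make P1(t) exactly
  invariant to swapping group labels (t enters only through t²) and keep
  the constrained M-step monotone in the likelihood (coordinate ascent on
  the EM lower bound with the ratio clipped at its floor). On null-only
  synthetic data π₁ collapses toward 0 and essentially no gene reaches
  P1(t) ≥ 0.8; on planted 4-fold effects at n = 5/sex detection exceeds
  90%. The precise empirical-Bayes machinery used to produce the original
  posterior values is not published alongside the thresholds it fed, so
  this model is a documented stand-in with the same interface, not a claim
  of equivalence.
- **Call gates** (both inclusive): differential expression
  |fold| ≥ 1.5 & P1(t) ≥ 0.8; sexual dimorphism |fold| ≥ 2.0 & P1(t) ≥ 0.8.
  Linear folds are reported as 2^|log2fc| with the sign carried separately
  ("repressed 3.0-fold" rather than 0.33-fold). Genes with zero counts in
  every sample are dropped before fitting and reported "not assessed".

## Pre-ranked enrichment

Ranking is by signed log2 fold-change, descending, ties broken
lexicographically by gene id for determinism. The running sum is the
unweighted membership walk (+1/N_h at hits, −1/(N−N_h) at misses), which
ends at exactly 0; ES is the value of maximal absolute magnitude (earliest
on ties), and the leading edge is the hits at/before a positive extremum or
at/after a negative one. A fold-change-weighted variant is deliberately out
of scope for the default statistic: the membership walk is the form being
emulated. Significance uses gene-set permutation (random size-N_h sets from
the ranked universe) with the add-one rule
p = (1 + #{|ES_null| ≥ |ES_obs|}) / (n_perm + 1), two-sided in |ES|. Null
ES values are computed with a closed-form evaluation at hit boundaries
(between hits the walk only decreases, so extrema occur just before/after
hits), vectorized over permutations; tests pin this formula to the full
walk. When the positive and negative extrema of a walk tie in magnitude to
within floating-point error the two evaluation orders may report opposite
signs; only |ES| enters the p-value, so this has no inferential effect.

## Neighborhood detection

The track is the per-chromosome cumulative sum of DE log2 fold-changes in
(chrom, TSS, gene id) order; non-DE genes contribute 0 and carry the score,
and the score resets on each chromosome, so the final value per chromosome
telescopes to the sum of its DE log2 fold-changes (a tested conservation
law). Strand is ignored for ordering and sign — the procedure is purely
TSS-positional.

Visual identification of "dramatic" rises and falls is formalized as:
maximal runs of same-sign DE contributions, tolerating up to `max_gap`
(default 2) intervening non-DE genes, requiring ≥ `min_genes` (3) DE genes
and total |Δscore| ≥ `min_magnitude` (4 log2 units). One refinement keeps
the reported boundaries tight: terminal run members with |log2fc| below
`trim_frac` (0.5) × the run's median |log2fc| are trimmed, so an isolated
weak background gene bridged onto a strong block by the gap tolerance does
not dilate its boundaries. The cost is that genuinely tapering cluster
edges (terminal members under half the block's median effect) would also
be trimmed — acceptable for detecting coordinated blocks, and all four
parameters are exposed. No statistical null for segments is provided;
segment significance is future work.

## pDRE scanning and peak integration

The PWM is L×4 (A,C,G,T) frequencies, renormalized after a pseudocount
(default 0.01); matrices shorter than the 5-bp GCGTG core are rejected.
Conservation weights follow the matrix-similarity-score convention:
c_i = (100/ln 4) · Σ_b f(i,b) ln(4 f(i,b)), clipped at 0 — exactly 0 for a
uniform position, →100 for a deterministic one. A window scores
Σ_i c_i f(i, b_i), min–max normalized by the per-position minimal/maximal
attainable sums, so the consensus scores exactly 1.0 and the
anti-consensus exactly 0.0. Both strands are scanned (reverse-strand hits
reported at forward-strand half-open coordinates); windows containing N are
skipped; the functional cutoff defaults to MSS ≥ 0.85, exposed because the
emulated analysis also quotes 0.856 in one place. The bundled
`default_test_pwm` (uniform flanks around a fixed GCGTG core) is synthetic
and for testing only — under it a window hits iff it contains the exact
core, with expected background rate 4⁻⁵ per strand-position on i.i.d.
sequence.

Peaks with FDR ≤ 0.05 are assigned to every gene whose body + 10 kb
TSS-side flank they intersect (both parameters exposed; no single window
reproduces every published phrasing of "within" a gene, so the choice is
logged). A peak "contains" a pDRE only under full containment of the hit
window — deterministic and conservative at peak edges. Sex partitions
(both / male-only / female-only / neither) are checked for disjointness
and count conservation over the universe.

## Convergence classification

For a baseline sex-biased gene, the dimorphism index d = log2(male/female)
is updated additively: d_treated = d_baseline + log2fc_male − log2fc_female
(exact identity, tested). Classes: `unchanged` iff neither per-sex response
passes the DE gate; otherwise the net change Δd is *converging* when it
opposes the sign of d_baseline. Converging genes are `lost_dimorphism`
(both sexes respond), `feminized_male` (only males respond) or
`masculinized_female` (only females respond); non-converging responses are
`reinforced`. Convergence may overshoot zero: a male-biased gene repressed
5.8-fold in males and induced 9.8-fold in females ends with a female-biased
index, and is still a loss of the original dimorphism — so
`lost_dimorphism` guarantees |d_treated| < |d_baseline| *or* a sign flip,
not a strict shrink. The classifier is exactly symmetric under swapping
the sexes (responses swapped, bias and index negated). Fixed gene panels
(hepatokines, albuminoids, fetal markers, Mups, hemoglobins, dimorphism
regulators) are summarized as signed folds with a majority-sign consensus
("mixed" on ties), one contrast at a time.

## Synthetic data: what it emulates, and what it does not

The generators produce the study-shaped inputs with planted truth:

- **Atlas** (defaults: 2,000 genes × 96 tissues, 181 planted specific
  genes): background signal i.i.d. uniform on [50, 3000] for every tissue
  (ceiling safely below the 5,000-unit threshold), planted genes set to
  their own other-tissue maximum + 6,000 before Gaussian noise (sd 200).
- **Counts** (2,000 genes, n = 5/sex): negative binomial with lognormal
  base means (median 500, σ 0.8), common dispersion 0.05, uniform
  [0.7, 1.3] library factors, and planted sex multipliers 2^(±1.5/2) per
  sex (total ratio 2^1.5, comfortably above the 2-fold dimorphism gate).
- **Genome** (2 chromosomes × 500 genes at 20 kb spacing): one consecutive
  8-gene block at log2FC −4 (P1(t) = 0.99); background genes DE with
  probability 0.1, |log2FC| uniform on [log2 1.5, 2] with random sign —
  consistent with the DE gate; ~30% of genes get a 500-bp ChIP peak over
  the TSS at FDR 0.01, always male for cluster genes, otherwise
  male/female/both; with probability `dre_density` (0.5) a peak gene gets a
  consensus DRE planted at its TSS on a random strand. Accidental GCGTG/
  CACGC cores are scrubbed from peak intervals *before* planting, so
  pDRE-in-peak truth counts are exact; the scrubbed sequence is exactly
  what the FASTA contains (no hidden state). Gene spacing exceeds
  flank + peak extent, so planted peak→gene links are unambiguous.

One global seed fans out via `SeedSequence(seed, spawn_key=(k,))` with
fixed per-component keys; fixed seeds give bit-identical outputs.

What passing these tests does **not** show: real atlases have correlated
tissues and probe-level artifacts; real counts have gene-wise dispersions,
batch structure and library-composition effects; real genomes have GC
structure, repeat content, variable gene density and overlapping genes;
real ChIP peaks have variable width and scores. The planted-truth results
certify the algorithms' correctness and calibration under their stated
models, not performance on any particular real data set.

## Problem sizes and numerics

Monte-Carlo checks use 2,000-gene count matrices, 500-gene chromosomes
over 20 seeds, 200 × 499 permutation replicates and 5-kb brute-force scan
comparisons — sizes chosen so the full suite and the acceptance script
each run in well under a minute of compute per stage while leaving the
estimated rates stable to the tolerances asserted. EM runs at most 200
iterations with relative tolerance 1e-8 and a σ₁/σ₀ floor of 2;
permutation p-values are never 0 by the add-one rule; enrichment and
ΔSignal oracle comparisons are exact (same arithmetic on the same floats),
while MSS oracle comparisons allow 1e-9 for summation-order differences.
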