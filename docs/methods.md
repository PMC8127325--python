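# Methods

## Scientific setting

Essential genes — those whose single knockout is lethal or severely
deleterious — show distinctive intron architecture: short first introns,
more introns per gene, elevated GC-dinucleotide ("GC motif") density in
the first intron, and a low frequency of non-canonical (non GT..AG)
splice boundaries. `introness` implements the complete analysis around
that observation: intron extraction from genome + annotation, the seven
per-gene intron features, a convolutional intron-sequence classifier with
gene-level score aggregation, a feature-based ensemble network,
group-comparison statistics, and a synthetic corpus generator that plants
the effect structure so the whole pipeline can be exercised and validated
end to end without external data.

## Labels

Gene labels follow an OGEE-style study table: per gene, the number of
large-scale studies calling it essential out of the total. Three-way
categories (essential / conditional / nonessential) are kept for the
feature analysis. For binary classification, conditional genes essential
in fewer than half of studies are discarded and the remainder are grouped
with essential genes. At exactly half the gene is kept as essential (the
"fewer than half are discarded" reading); this boundary rule is
configurable (`assign_label(..., half_is_essential=False)`).

## Intron extraction

One transcript per gene contributes introns: the mRNA with the maximal
total CDS length, ties broken by lexicographically smallest transcript
id. Introns are the gaps between consecutive exons, reverse-complemented
for minus-strand genes and numbered 1..n in transcript 5'→3' order.
Coordinates are 0-based half-open internally; GFF3 conventions are
converted at the parser boundary. Overlapping or unsorted exons and
introns outside their contig are hard errors naming the transcript.

## Features

* **GC-motif density** — occurrences of the dinucleotide "GC" per base,
  counted by exhaustive overlapping scan. The motif string is
  configurable; ambiguity codes never match.
* **GC content excluding motifs** — (#G + #C − 2·n_GC)/L, which obeys
  `gc_content = gc_content_excl_motifs + 2·gc_motif_density`.
* **Splice dialect** — an intron is "unusual" at the 5' end when it does
  not begin with GT, at the 3' end when it does not end with AG; an
  ambiguity code at a boundary counts as unusual (conservative and
  deterministic).
* **CpG islands** — Takai–Jones sliding window: a 200-bp window
  qualifies at GC ≥ 0.55 and observed/expected CpG ≥ 0.65
  (Exp = #C·#G/window); runs of qualifying windows are unioned, regions
  closer than 100 bp merged, each region trimmed one base from *both*
  ends until the whole region qualifies, and regions ≥ 500 bp reported.
  The trim order is not fixed by the source algorithm; symmetric
  trimming was chosen for determinism. Sequences shorter than the
  window return an empty list rather than an error.
* **Per-gene vector** — average intron size, intron count, total
  intronic bp, GC-motif density and motif-excluded GC content for the
  first intron and as unweighted means over later introns (ordinal ≥ 2).
  Later-intron fields of single-intron genes are missing (NaN), imputed
  downstream. Group-level densities are unweighted means of per-intron
  values, matching a box-plot presentation, not pooled base counts; the
  first/later *ratios* are invariant to that choice.

## Sequence models

Both classifiers are small numpy networks trained with Adam on softmax
cross-entropy with optional L1/L2 penalties and inverted dropout; all
randomness flows from explicit seeds.

**Convolutional intron classifier.** f(s) = net(pool(rect(conv(s)))) on
one-hot encoded windows (columns A,C,G,T; N/ambiguity/padding rows are
uniform 0.25, the DeepBind padding convention). Two models are trained,
one on the first and one on the last 1,000 bp of each intron (window
length configurable); introns shorter than the window are padded.
Pooling is *average* pooling across sequence positions — one value per
filter, the cumulative motif presence. Defaults: 128 filters of width
24, 128 fully connected units, dropout 0.2, L2 1e-6, ReLU, 30 epochs,
batch 64. The Adam step is 1e-2 rather than the customary 1e-3:
average pooling divides convolution gradients by the ~10³ sequence
positions, and at 1e-3 the 10–30-epoch budgets underfit badly (pilot
intron AUC 0.70 vs 0.90 at 1e-2). The L1 strength defaults to 0.

Splits are made at the gene level, stratified by binary label: 20% of
genes to the test set, the rest dealt into three CV folds, so all introns
of a gene share one partition and no gene-specific signal leaks.
Training batches are class-balanced by oversampling the minority class
with replacement to the majority count each epoch, interleaved so every
batch is 50/50 within ±1. Hyperparameter selection is a 36-point grid —
dropout {0, 0.2, 0.5} × conv window {16, 24} × activation {relu, elu} ×
L2 {1e-4, 1e-6, 0} — scored by mean validation AUC over the three folds
(ties toward smaller L2, then smaller dropout). The grid axes are the
four searched hyperparameters; the concrete values are this package's
choice and include the default (winning) configuration.

**Gene scoring.** The majority classifier scores a gene as the mean of
its introns' essentiality scores; the double classifier pools intron
scores from both window models (equal to averaging the two per-model
gene means, since both models score the same introns). ROC curves sweep
all distinct thresholds with ties grouped, making the trapezoidal AUC
identical to the Mann–Whitney U / (n₁n₂) statistic with half-credit for
ties; this equality is asserted against an exhaustive pair-counting
oracle.

**Feature model.** The 7 features are z-scored with training-set
statistics; missing later-intron fields are imputed with the training
median and a missingness indicator is appended (single-intron genes are
kept, not dropped); constant features map to 0. The network is a stack
of fully connected rectified layers chosen from a 16-point grid
({1,2} layers × {32,128} units × dropout {0,0.2} × L2 {0,1e-4}) by
threefold CV, trained 30 epochs at batch 64. The final predictor
averages 10 members that differ by initialization seed and
bootstrap-resampled training sets (how the members differ is otherwise
unspecified; bootstrap + seed is the standard variance-reduction
recipe).

## Synthetic corpus

The generator's defaults are the study conditions:

| parameter | essential | conditional | nonessential | basis |
|---|---|---|---|---|
| introns per gene (mean, shifted Poisson) | 12.9 | 11.0 | 9.2 | observed introns-per-gene of curated human genes |
| first-intron mean length (bp) | 1,200 | 2,400 | 3,960 | 3.3× nonessential/essential ratio; absolute scale is a model choice |
| later-intron mean length (bp) | 700 | 900 | 1,100 | ordering only |
| GC-motif density, later introns (/bp) | 0.060 | 0.058 | 0.056 | anchor values |
| GC-motif density, first introns (/bp) | 0.081 | 0.0708 | 0.0633 | first/later ratios 1.35 / 1.22 / 1.13 |
| P(unusual 5') | 0.010 | 0.020 | 0.035 | ordering essential < conditional < nonessential |
| P(unusual 3') | 0.008 | 0.015 | 0.030 | same ordering |
| class motif rate (/bp) | 0.003 | 0.002 | 0.0004 | learnable CNN signal |

Lengths are log-normal (σ = 0.7 on the log scale — right-skewed, mean
well above median, as real intron lengths are) with the mean
parametrized exactly (μ = ln mean − σ²/2) and a floor at the minimum
intron length (70 bp). Background base composition is i.i.d. at 38%
G+C. Study counts per gene are drawn so conditional genes genuinely
disagree (essential fraction uniform-ish in (0,1)), exercising both the
discard and the regroup branches of the label rule.

**Exact density planting.** `synthesize_intron` makes the *expected*
measured GC-motif density exactly equal to its target: boundary dinucleotides,
motif alphabet (no internal "GC", first character ≠ C, last ≠ G) and a
≥3-bp spacing between planted "GC" pairs guarantee that every base pair
of the final sequence is either an independent chance GC (probability
(base_gc/2)²) or deterministically not GC, so the number of planted
pairs K solves a linear equation and is randomized between floor and
ceiling. One consequence: the unusual-boundary choices exclude the
"GC" 5' donor (a real minor splice class) because it would break the
accounting; unusual sites are drawn from the remaining non-canonical
dinucleotides (including the genuine minor-class AT..AC).

CpG-island structure is *not* separately planted; island presence
emerges from the GC parameters, and the report simply describes it.

`emit_corpus` writes one contig per gene (random flanks, 150-bp exons
interleaved with the planted introns, CDS = exons), reverse-complementing
minus-strand genes, plus a decoy one-exon transcript on every fifth gene
so the longest-CDS rule is exercised; extraction must recover every
planted intron byte-for-byte, which the round-trip tests assert.

**What the generator does not emulate:** real base composition and
repeat content, positional length trends within a gene, splice-site
consensus beyond the terminal dinucleotides, linkage between features,
or real effect-size noise. Passing tests therefore demonstrate that the
pipeline recovers structure that is present, not that the real-data
effect sizes or AUCs would be reproduced.

## Statistics

Group comparisons use the two-sided Mann–Whitney rank test (the standard
companion of notched-box summaries of skewed length data): exact
enumeration of group assignments for n ≤ 12 with the
deviation-from-null-mean two-sided rule, otherwise the tie-corrected
normal approximation. Notches are median ± 1.57·IQR/√n. Raw p-values
are reported; Benjamini–Hochberg adjustment is available behind a flag.
A permutation-test alternative for proportions is intentionally not
provided; rank tests on 0/1 flags are equivalent to proportion tests up
to the normal approximation.

## Problem sizes and verification

The planted-parameter recovery checks run at 2,000 genes per class
(~66k introns, ~65 Mb of sequence), where the sampling error of the
length-ratio estimate is ≈2.5% and of the density ratios ≪1%, inside
the 5% acceptance tolerance. The convolutional checks run on a reduced
corpus — 600 genes, 500-bp windows, 32 filters, 10 epochs — chosen as
the smallest configuration at which motif learnability is comfortably
demonstrated; the feature ensemble trains on the full-scale corpus's
gene vectors. `scripts/acceptance.py` recomputes the four ratio targets
from scratch (generate → emit → extract → features) for any seed.

## Known limitations

* The numpy networks are CPU-only and single-threaded beyond BLAS; they
  are sized for corpus-scale experiments, not genome-scale training.
* `read_genome` loads contigs fully into memory (fine for the corpora
  here; use a faidx-style reader for multi-gigabase genomes).
* Grid-search CV retrains a model per grid point per fold (108 fits for
  the CNN grid) and is therefore a deliberate, expensive opt-in
  (`train-cnn --grid-search`).
* The double classifier's advantage over the single majorities is a
  soft, stochastic property; it is asserted with a small slack.
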