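# Methods

## Screen model

The simulator emulates bacterial killing-efficiency screens in which a
pooled library of 20-nt spacers targets NGG-adjacent sites on both
strands of a genome. Guide targets are every 20-mer immediately 5′ of an
NGG, enumerated on both strands; overlapping PAMs each yield their own
site, and sites whose requested flanking window would cross the contig
boundary are dropped rather than padded, so every encoded window is fully
defined. Genomes are linear and single-contig.

Sequencing of one sample is modelled in two stages:

1. **Library composition.** Initial guide proportions are drawn
   log-normal(0, σ) and renormalized. σ (`abundance_dispersion`, default
   1.0) controls how skewed the cloned library is; at σ = 1 the 10th/90th
   percentile abundance ratio is ≈13×, a realistic spread for pooled
   libraries and the mechanism by which some guides end up with very few
   control reads even at high mean coverage.
2. **Selection and sequencing.** Control samples are
   multinomial(depth, p₀) draws. Experimental samples re-weight p₀ by
   2^(−k·activity) (depletion) or 2^(+k·activity) (enrichment),
   renormalize, and draw a fresh multinomial. k (`selection_strength`,
   default 1.0, log2 units per activity unit) sets how many doublings of
   relative abundance one activity unit buys. Replicates are independent
   draws; one child random stream per sample descends from the screen
   seed, so individual replicates are reproducible.

Default replicate structure is one control and nine experimental samples
at a few-hundred-fold mean read coverage per guide, matching a deep
depletion screen with a single pre-selection control. The simulator does
not model PCR/amplification bias, read errors, or multi-contig
assemblies; counts are exchangeable multinomials given the proportions.
Real screens have over-dispersion between replicates beyond multinomial
noise, so passing tests here demonstrate correctness of the analysis
logic under the stated model, not robustness to every artefact of real
data.

## Planted ground truth

Activity is a linear function of local sequence plus Gaussian noise:
baseline + positional di-nucleotide weights + an optional AT-richness
penalty over a flanking window. Positions are indexed from the first PAM
base (spacer −20..−1, PAM 0..2, downstream ≥3). The default model plants:

* a T-richness bonus at PAM-proximal spacer positions −8, −6, −4, −2
  (T-rich seed regions favoured, as seen across bacterial Cas9 screens);
* random per-base preferences at downstream positions 3, 5, 7 — the
  region immediately 3′ of the PAM where protein–DNA contacts are known
  to modulate activity;
* weak random effects at PAM-distal spacer positions −14, −12, −10.

Weights sit on alternating (non-overlapping) di-nucleotide positions so
every planted effect is identifiable from a marginal mean — overlapping
di-nucleotides share a base and would bias each other's cell means. Each
structured position also carries a small random interaction term that a
purely additive (per-base) model cannot express, giving the network
something beyond the ridge surrogate's reach. The resulting signal has sd
≈0.75 log2 units over random sequence; the default per-site noise sd of
0.2 is roughly a quarter of that scale.

## Scoring

Scores are between-condition differences of centred log-ratio (CLR)
transformed proportions, in log base 2 throughout so the score reads
directly as a log2 fold change. The prior is 0.5 per cell (the standard
Dirichlet-multinomial convention). Monte-Carlo mode draws proportions
from Dirichlet(counts + prior) per sample and instance, takes the
difference of condition means within each instance, and reports the
per-guide median across instances — well defined with a single control
replicate, and converging to the deterministic point estimate, which the
tests use as a closed-form oracle. `active_positive` orientation flips
the sign for depletion assays so depletion and enrichment data share a
"higher = more active" scale.

Low control counts limit the attainable score: with a control count of 1,
only an experimental count of 0 can produce a positive depletion score.
This ceiling property is tested as strict monotonicity of the score in
the control count when the experimental count is pinned at zero.

## Curation

`apply_cutoff` retains guides whose *mean* control count is ≥ C
(non-strict, so C = 1 keeps anything seen at least once on average). The
sweep re-scores each filtered table — the CLR denominator changes with
the retained set, so scores are recomputed, never subset — then encodes,
splits off a 20% held-out fraction, and k-fold cross-validates a
regressor on the training portion. The chosen C maximizes mean CV
Spearman, ties resolved toward the smallest C (discard less data at equal
performance). Each variant's split seed derives from the base seed plus
the retained guide-id set: variants with different data re-split
independently, while inert cutoffs (no guide removed) reproduce identical
metrics. The sweep regressor defaults to the ridge surrogate because a
1..100 sweep at 5 folds needs 500 fits and the conclusion under test is
about the data, not the architecture.

## Windows, encoding and splits

Windows are extracted in spacer orientation: U upstream nucleotides, the
spacer, the PAM verbatim if included (the N base unmasked), and D
nucleotides beyond the PAM; minus-strand windows are the reverse
complement of the corresponding reference slice. D > 0 requires the PAM,
since those bases sit beyond it. Encoding is one-hot 4×N with row order
A, C, G, T; shape mismatches fail at dataset construction, before any
training.

Splits deduplicate by exact window sequence first (first occurrence kept,
preserving data volume) so no identical input can appear on both sides,
then assign ⌊n·fraction⌋ guides to the held-out test set. The leakage
report gives the minimum and distribution of pairwise hamming distances
between test and train spacers; it is descriptive — no filtering beyond
exact-duplicate removal — because near-duplicate handling is a judgement
call best left to the analyst.

In the flank-length sweep, the upstream curve extends the bare spacer
(no PAM) and the downstream curve always includes the PAM with d bases
beyond it; both are reported as deltas against the single shared
spacer-only baseline, which avoids a discontinuity at d = 0 and makes the
two curves directly comparable.

## Regressors

The hybrid network passes the one-hot input through an initial
convolutional block (Conv1D → LeakyReLU → max-pool), then branches: a
stack of further convolutional blocks on one side, a bidirectional GRU on
the other; each branch ends in two dense layers with dropout, and the
concatenated branches feed a single linear output node. Training is Adam
on mean squared error, learning rate 0.0005 and batch size 1,024 by
default (settings for large datasets; the batch clamps to the dataset
size). Labels are standardized internally and predictions mapped back to
score units. All layer sizes are configuration-exposed; nothing is
hard-coded. The network runs on a small reverse-mode autodiff engine over
numpy arrays (`_nn.py`) — float64, seeded, deterministic given a fixed
seed — with parameters initialized Glorot-uniform.

The desk-scale configuration (`tiny_config`) uses pool width 1 in the
initial block: on short windows the planted signal is position-specific
and early pooling discards exactly that information. Capacity is kept to
a few thousand parameters so the model generalizes from ~2,000 guides;
epoch count is the main tuned hyper-parameter, selected by
cross-validation in real use.

The ridge surrogate is a closed-form linear map on the flattened one-hot
features (penalty enforced > 0 to keep the system non-singular). It is
deterministic, costs milliseconds, and recovers planted additive
preferences up to the one-hot column collinearity (weights are compared
within-position-centred).

## Evaluation

Performance metrics are Spearman ρ (primary) and Pearson r, computed with
scipy; folds are disjoint seeded KFold partitions. A constant prediction
vector makes Spearman undefined; such folds are reported as missing
rather than zero so they cannot silently deflate or inflate a mean.
Di-nucleotide profiles report the mean label per (PAM-relative position,
di-nucleotide) with per-cell counts. Error-by-count bins default to
integer widths up to a count of 20 and widths of 5 beyond, configurable;
prediction error is stratified by sign because the dynamic-range ceiling
affects would-be-positive predictions specifically.

## Problem sizes and numerical choices

The packaged studies use 2,000-guide libraries drawn from ~120-kb random
genomes (GC 0.5), 37-nt model inputs (U=3, PAM, D=11), 5-fold CV, and
40-epoch hybrid training — sizes at which every pipeline stage's
behaviour is measurable while a full run stays in the minutes range on a
single CPU. The cutoff-sweep study uses 115× mean control coverage, which
places ~10% of guides below 20 control reads — the regime the curation
step exists for. Monte-Carlo scoring agreement is checked at 256/1,024/
4,096 instances; 4,096 instances agree with the closed form to well
under 0.1 log2 units on toy tables.

## Known limitations

* The generative model is an emulation target: real libraries are
  experimental and their composition process is not observed.
* Exact-match counting ignores sequencing errors; reads matching two or
  more distinct spacers are discarded by declared convention, as the
  correct attribution is unknowable without alignment.
* The autodiff backend is single-threaded numpy: adequate at desk scale,
  not a GPU training stack.
* Scores from a single control replicate inherit that replicate's
  sampling noise fully; the package reports mean control counts so
  analysts can judge the regime, but cannot manufacture precision that
  the design lacks.
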