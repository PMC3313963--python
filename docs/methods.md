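# Methods

## The problem and the model

MHC class II molecules such as the NOD mouse's I-A<sup>g7</sup> and
human HLA-DQ8 present peptide antigens to CD4⁺ T cells through an open
binding groove that engages a 9-residue core register, while the
experimentally mapped epitopes around those cores vary from about 9 to
30 aa. `epicore` treats core identification and core-based prediction as
one pipeline built on a single primitive: the similarity of two
nonamers A and B under a residue substitution matrix,

    S′(A, B) = Σ_{i=1..9} wᵢ · Score(A[i], B[i]),
    S′(A, B) := 0 if the sum is negative.

The clamping is applied per pair, before any averaging, so all derived
scores are non-negative. A query nonamer's model score is the mean of
its clamped similarity over all training cores; the underlying
assumption is that short peptides of similar sequence present similar
shapes and chemistry to the groove and the T-cell receptor, so proximity
to the cloud of known binders in substitution-score space predicts
binding. Scores are carried as float64 with no rounding until report
time (human-readable reports print 4 decimals).

## Core alignment by similarity-driven Gibbs sampling

One window P_i per epitope is maintained. After uniform random
initialization, the sampler repeatedly visits all epitopes in a fresh
random permutation per pass; for the visited epitope every window is
scored by its mean clamped similarity to the other epitopes' current
cores (unweighted starting matrix — the sampler runs before any
training), and the assignment moves to the argmax, smallest offset
winning ties for determinism. Convergence is a full pass with zero
assignment changes, with a 200-pass cap. This replaces the classical
PSSM log-odds sampling objective with the average similarity score;
there is no insertion/deletion tolerance and no background frequency
model.

Because every update is an argmax with all other assignments fixed, the
total objective Σ_i Score(P_i) is non-decreasing across accepted
updates, but the landscape has strong *phase-shift* local optima: a
whole data set can lock in one residue off the true register, since the
shifted consensus is self-consistent. The sampler therefore runs
multiple independent restarts (default 5) from one seeded generator and
keeps the run with the highest total objective. Epitopes identical in
sequence are all retained through sampling; deduplication by sequence
happens only on the output core list used for training.

A single 8-aa epitope is handled by growing it one residue on each side
from its source protein into a decapeptide; an 8-mer abutting a protein
terminus (or lacking its protein sequence) is dropped with a warning
rather than extended asymmetrically.

## Data sets and labels

Positives for training are the deduplicated assigned cores. Negatives
are every 9-mer window of the same source proteins *not fully
contained* in any epitope span of that protein — containment, not
overlap, defines both this exclusion and the epitope-level hit rule
(an epitope is a hit when at least one predicted nonamer lies fully
inside it). Negatives are deduplicated by sequence and any negative
identical to a positive core is removed, so no sequence carries both
labels. All files use 1-based inclusive coordinates; internally
everything is 0-based half-open.

Windows containing residues outside the 20-letter standard alphabet
(X, B, Z, U, \*) are excluded from scoring, training and negative sets
with a logged count, since the substitution matrix defines no score for
them. Residue case is normalized to uppercase on input.

## Greedy training: WT and MaM

The training objective is leave-one-out (LOO) sensitivity at a fixed
specificity of 90%: each positive is scored against the remaining
positives, each negative against all positives; the cutoff is the
smallest observed score whose strict false-positive fraction is at most
10%, and Sn is the fraction of positives strictly above it.

Weight training (WT) proposes w_k ± 1 for a uniformly random position
and direction; matrix mutation (MaM) proposes ±1 on one random matrix
entry, applied jointly to (a, b) and (b, a) so the similarity stays
order-independent. A proposal is accepted only if Sn strictly
increases; ties are rejected. Weights are clamped non-negative (a −1
proposal on a zero weight is auto-rejected) because a negative position
weight would invert residue-similarity semantics at that position. The
default stage order is WT then MaM; an alternative order or a repeated
schedule can be configured.

Random ±1 proposals cannot certify a local optimum, so "no further
improvement" is operationalized as a run of 1000 consecutive rejections
(configurable), with a hard cap of 20000 proposals per stage.

Because weights and matrix entries start integer and move in integer
steps, every raw score is an exactly representable integer-valued
float; the incremental rescoring the trainer uses (adding the delta of
the one touched position or residue pair) is therefore bit-identical to
a full recomputation — an equality the test suite asserts — and
rejected proposals are bit-exact no-ops because candidate score arrays
are discarded, never written back. Training is fully determined by
(data, config, seed).

## Evaluation and calibration

Sn, Sp, Ac and MCC use the standard confusion-matrix definitions, with
MCC defined as 0 when any denominator factor vanishes. Classification
is strict (`score > threshold`) everywhere, which keeps calibration and
prediction consistent: a tier cutoff calibrated for Sp ≥ 95% still
achieves it at prediction time. ROC curves sweep the sorted union of
observed scores (with ±∞ sentinels) and AROC is the trapezoidal area,
which equals the Mann–Whitney U statistic scaled by n⁺n⁻ including the
half-credit tie convention.

Three cutoffs are calibrated on the final model's LOO table at
specificities 97% (high), 95% (medium) and 90% (low); medium is the
default tier. The ordering high ≥ medium ≥ low always holds; on small
or heavily tied score tables adjacent tiers can coincide, so strict
ordering is not enforced.

Repeated stratified n-fold cross-validation mixes positives and
negatives, splits them into n class-balanced parts per repeat, and
holds each part out once. By default only the core-set membership is
refit per fold — the held-out nonamers are scored against the training
folds' positives using the already-trained matrix and weights — because
retraining WT/MaM inside every fold is available behind a flag but is
rarely informative at these data sizes and is far more expensive.
Per-repeat seeds derive from the master seed; 20 repeats is the default
protocol. Cross-haplotype evaluation scores one haplotype's labeled set
against the other haplotype's model (cores, matrix, weights and
thresholds all foreign).

## The synthetic-data generator

The generator emulates the structure of the curated training sets with
known ground truth. A motif profile is 9 position-specific residue
distributions: anchor positions (default 9, 8 and 4, mirroring a
dominant P9 with weaker companions) concentrate at least the configured
anchor strength (default 0.9) on one random residue; non-anchor
positions follow the background, uniform over the 20 residues by
default with a natural-abundance option. Epitopes are background flanks
around one profile-drawn core at a uniform random offset (lengths
12–25 by default, matching the typical literature range), each embedded
at a recorded locus in a 120-aa background host protein so negative
windows come from realistic flanking sequence. A configurable fraction
(default 5%) of epitopes is emitted as 8-mers — the core minus one
terminal residue — to exercise the extension rule.

What the generator does **not** emulate: real proteome composition and
homology between source proteins, multiple epitopes per protein,
binding-affinity structure beyond a single sequence motif, and
curation noise in literature coordinates. Passing tests on synthetic
data therefore demonstrate the correctness and internal consistency of
the algorithms (recovery of implanted registers, monotone training,
calibration semantics), not the field performance of models trained on
curated epitopes.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run the pipeline at sizes
chosen to exercise every stage meaningfully while staying quick: Gibbs
recovery on 50 epitopes with 5 restarts; training monotonicity on 300
unique positive cores against 3000 background negatives with the
default stop rule; cross-validation at 4/6/8/10 folds × 20 repeats on
120–300 positives; cross-evaluation on 150-positive foreign sets. The
acceptance script derives every stream of randomness from its `--seed`
argument and writes all measured quantities to JSON.

## Known limitations

- Greedy ±1 hill-climbing finds local optima only; the paper-protocol
  objective (Sn at one Sp anchor) is a step function of the threshold,
  so small data sets produce plateaus where training stops early.
- The LOO objective reuses the same negatives at every step, so very
  long MaM runs can overfit matrix entries to the negative sample;
  held-out evaluation in the tests guards the defaults.
- Scoring is ungapped and fixed-length by construction: register
  shifts, core lengths other than 9, and modified residues are out of
  scope.
- Threshold tiers are calibrated on LOO scores of the training set; on
  foreign proteomes with different composition the realized specificity
  may differ from the nominal tier.
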