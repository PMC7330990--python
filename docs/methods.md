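# Methods

## Problem and model

`pepmhc` predicts the binding affinity between short peptides (8–37
residues over the 20-letter amino-acid alphabet) and MHC molecules, one
regression model per allele.  Measured affinities are IC50 values in nM;
the model regresses the bounded log-transform

    y = 1 − log(IC50) / log(cap),        cap = 50 000 nM,

so y = 1 at 1 nM (strong binder) and y = 0 at the cap.  The transform is
order-reversing: an assay bound "IC50 < b" becomes a *lower* bound on y and
"IC50 > b" an *upper* bound.  Predictions are reported both in y-space and
back-transformed to nM via ic50 = cap^(1−y).

The network is a small AWD-LSTM: a learned 50-dimensional embedding over a
22-token vocabulary (20 residues + PAD + BOS), one LSTM layer with 64
hidden units, regularized by embedding dropout (whole-row, 0.1),
variational input dropout (0.25), weight-drop on the recurrent matrix (one
mask per sequence, 0.3) and output dropout (0.1).  The weight-drop rate
was tuned once on a development benchmark — 0.5, the value typical of
protein-scale models, over-regularizes a 64-unit layer and cost ~0.08 of
held-out rank correlation.  Peptides are read N→C
with a prepended BOS token and no EOS; the recurrent state at the final
residue feeds the head directly.  Two heads share this backbone:

* **Language model** — a linear decoder producing a next-token
  distribution at every position; quality is held-out perplexity
  (exp mean cross-entropy; 1 = perfect, 20 ≈ uniform chance) and argmax
  accuracy.
* **Regressor** — masked concat pooling, `[h_last ‖ max_t h ‖ mean_t h]`
  over the first `length` positions only (PAD positions never contribute;
  this makes predictions exactly padding-invariant), followed by two fully
  connected layers 192 → 64 → 1 with ReLU and dropout 0.1.  The output is
  an unconstrained real in y-space, clipped to [0, 1] only when converting
  to nM.

Default parameter counts: 31 970 (LM) and 42 957 (regressor); both are
pinned in the test suite to catch architecture drift.

The implementation is plain numpy with hand-written backpropagation; at
this model scale a deep-learning framework is unnecessary, and every
gradient path is validated against central finite differences in the unit
tests (relative agreement ~1e-6 on non-kink points).

## Censored loss

Quantitative records contribute an ordinary squared error (y_pred − y)².
Qualitative records contribute one-sided penalties: a lower bound in
y-space (from "IC50 < b") is penalized only when under-predicted,
max(0, y − y_pred)²; an upper bound (from "IC50 > b", e.g. a non-binder
known only as exceeding the assay limit) only when over-predicted,
max(0, y_pred − y)².  The batch loss is the unweighted mean.  The loss is
continuous, zero exactly on each branch's satisfying set, and its
(sub)gradient is 2·r with r the signed clipped residual.

Binder labels use the strict rule IC50 < threshold, with the conventional
thresholds 500 nM (class I), 1000 nM (class II) and 100 000 nM for assays
censored at a high bound.  For a censored record the stored bound stands in
for the measurement when labeling; a bound that straddles the threshold
("IC50 > 400" vs threshold 500) is resolved by the same rule, which is the
only option that needs no extra annotation.

## Training

All variants share one code path: {from-scratch | LM-pretrained} ×
{single | ensemble}.

* **Optimizer.**  Adam with decoupled (AdamW-style) weight decay and
  global gradient-norm clipping at 1.0, under a 1-cycle schedule: the
  learning rate ramps linearly from max_lr/25 to max_lr over the first 30%
  of steps and anneals to max_lr/10⁴, while beta1 cycles inversely between
  0.95 and 0.85.  Plain SGD with momentum was tried first and proved
  unusable at this scale: it underfits badly at stable learning rates and
  diverges at the rates needed to fit within a sensible step budget —
  recurrent nets under MSE-scale gradients want per-parameter adaptivity.
* **Learning rates.**  Established once with the built-in range test
  (exponential sweep over one pass; suggestion = one decade below the
  smoothed-loss minimum): peak 2e-2 for regression (200 epochs, batch
  128), 1e-2 for the LM (20 epochs).  The regression epoch count is set by
  convergence of held-out rank correlation on a development benchmark, not
  by the LM's.
* **Weight decay.**  0.01 during finetuning; 0.3 during LM pretraining.
  The strong LM value matters: without it Adam inflates backbone weight
  norms ~3×, the LSTM gates saturate, and finetuning from the pretrained
  weights *under*-performs from-scratch training.  With it, pretrained
  initialization is neutral-to-beneficial, as expected of transfer
  learning.
* **Discriminative fine-tuning.**  When starting from pretrained weights,
  layer groups (head / recurrent / embedding) get per-group learning
  rates divided by 2.6 per step down from the head, so the fresh head
  adapts fastest and the pretrained embedding slowest.  Disabled for
  from-scratch runs.
* **Ensembling.**  k = 10 members with identical architecture and
  hyperparameters, seeds derived from one master seed via
  `SeedSequence.generate_state`; the ensemble prediction is the arithmetic
  mean of member outputs in y-space (the space the loss lives in), then
  converted to nM.  By convexity of squared error the ensemble's MSE never
  exceeds the members' mean MSE.
* **Validation split.**  10% of peptides by md5 hash of the peptide
  string — reproducible across runs without storing split files, and
  identical peptides always land on the same side.  For degenerate corpora
  where the hash split empties one side (e.g. a single repeated peptide),
  held-out LM metrics fall back to the training peptides, with a warning.
* **Determinism.**  (seed, data, config) fully determine weights and
  predictions: model init, shuffling, dropout masks and member seeds are
  separate child streams of one `SeedSequence`.

## Evaluation protocol

AUC ROC is computed through the rank-sum (Mann–Whitney) identity on
average ranks — exactly the trapezoidal ROC area, ties counting one half —
and Spearman r as Pearson correlation of mid-ranks (scipy).  Both return
an explicit *undefined* marker instead of a number when degenerate (one
class only; fewer than two quantitative pairs or zero rank variance), and
undefined alleles are excluded from macro aggregates and listed in the
report.

Two aggregations over multi-allele benchmarks: **mean** (macro; unweighted
average of defined per-allele metrics — every allele counts equally) and
**overall** (micro; the metric on all rows pooled — large test sets
dominate, and scores are implicitly assumed comparable across alleles).
Spearman uses only exact (=) measurements; AUC uses all rows through their
binder labels.  Per-allele Spearman is reported only for alleles with more
than 25 quantitative measurements (configurable).

Confidence intervals are 95% empirical bootstrap (the basic /
reverse-percentile pivot interval, 2θ̂ − q₉₇.₅ , 2θ̂ − q₂.₅; a percentile
option exists for comparison), B = 1000 by default, resampling rows with
replacement *within* each allele so the allele composition is preserved.
Replicates on which the metric is undefined are dropped, with a warning if
they exceed 1%.  For single (non-ensemble) models run k times, the
multi-run summary reports the mean point estimate and a conservative
error: the maximum over runs of max(θ̂ − lo, hi − θ̂).

Train/test redundancy is audited by same-length positional identity:
a test peptide is flagged if some training peptide of equal length matches
it on ≥ 80% of positions.  Different-length pairs are never compared.

## Synthetic data

The generators make the whole pipeline testable with known ground truth.

* **Cleavage simulation.**  Each inter-residue site of a protein is cut
  independently; the probability comes either from a supplied per-site
  table (one row per protein, as an external cleavage predictor would
  emit) or from a residue-conditioned model with elevated probability
  (0.18) after hydrophobic/aromatic and basic residues (A F I L M V W Y K
  R) and 0.04 elsewhere, giving a mean fragment length near ten.
  Fragments outside 8–20 residues are discarded — a hard guarantee, not a
  tendency.  A repeat count allows multiple independent slicings per
  protein (default 1).  Input proteins can be drawn with human-proteome
  residue frequencies (`random_proteins`), which gives a pretraining
  corpus with learnable composition and boundary statistics.
* **Benchmark generator.**  Each synthetic allele hides an anchor-style
  position-specific score matrix over a 9-residue core: 2–3 anchor
  positions with scores ~ sharpness · N(0,1), the rest near-flat (scale
  0.1·sharpness).  A peptide's energy is its best core alignment — max
  over sliding windows for longer peptides, best offset *within* the core
  for shorter ones (so 8-mers remain scoreable under a 9-residue core).
  Energies map to IC50 through a logistic curve
  ic50 = cap^(1 − σ(a·(E − b))) with (a, b) standardized per motif so that
  ≈25% of random peptides fall below 500 nM — the binder share typical of
  class I training sets.  A standalone motif is calibrated from the
  analytic core-length energy moments; inside the benchmark generator the
  calibration is redone empirically on the benchmark's own peptides, since
  max-over-windows shifts the energy distribution of longer peptides.  Gaussian noise (default sd 0.05 on the energy scale) is
  added before the mapping; the noiseless energies are retained in a truth
  table for parameter-recovery tests.  With configurable probability a
  record is emitted as qualitative (">" at a censoring bound, default
  50 000 nM; 100 000 nM mimics HPV-style sets).  Test sets are
  decontaminated against training at the 80% same-length identity rule by
  rejection sampling.
* **Markov corpora.**  First-order residue chains with Dirichlet rows and
  stationary start distribution provide LM fixtures whose Bayes-optimal
  next-token accuracy is computable in closed form; a trained LM should
  approach it, and chance level is 1/20.

What the generators do *not* emulate: real anchor-motif correlations
between positions, allele relatedness (shared motifs across alleles),
length-dependent binding preferences, inter-assay noise structure, and the
true proteasome's context-dependent cleavage preferences.  Passing tests
therefore demonstrate that the machinery — tokenization, censored loss,
optimization, transfer, ensembling, metrics — recovers planted structure
at realistic sizes and noise levels; they do not certify accuracy on real
IEDB-style benchmarks.

## Numerical and design choices

* Strict alphabet: B, J, O, U, X, Z are rejected with position and
  character named; silent wildcarding would corrupt the regression.
* No weight tying between embedding and LM decoder (dimensions 50 vs 64
  make it impossible without an extra projection).
* Masked concat pooling is mandatory, not optional: pooling over padded
  windows would make predictions depend on batch composition.
* LM loss masks positions without a successor token; padded positions
  carry zero gradient everywhere by construction.
* The LR range-test rule is deliberately simple (smoothed-loss minimum,
  one decade back) and deterministic given a seed; it restores model
  parameters afterwards.
* Problem sizes in the verification scripts (n_train = 2000 per allele,
  300 test peptides, 3000-peptide Markov corpora, 200 bootstrap
  simulations at n = 500, 10⁶ cleavage fragments) are chosen to make the
  statistical assertions sharp at single-workstation scale.
* `lr_range_test` errors out if the loss is non-finite at the smallest
  rate (a data/model misconfiguration, not a schedule problem).

## Known limitations

* Per-allele models share no information across alleles; rare alleles
  with few measurements will be weak (the ensemble helps little there).
* The single-layer, 64-unit backbone saturates on very long class II
  peptides' context; the architecture is fixed by design.
* Interior-position determinants need a few hundred training examples
  before the recurrence localizes them; terminal positions are learned
  from far less data (the last hidden state exposes them directly).
* Bootstrap resampling treats rows as exchangeable within allele;
  correlated measurement errors (same lab, same assay) are not modeled.
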