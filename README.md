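# pepmhc

Per-allele peptide–MHC binding affinity prediction with small recurrent
sequence models.

Deciding whether a peptide binds a given MHC molecule is a central step in
epitope discovery and neoantigen prioritization.  `pepmhc` trains one
regression model per MHC allele on measured IC50 values (nM), using a
compact AWD-LSTM backbone — a learned residue embedding feeding a single
weight-dropped LSTM layer — with a concat-pooling regression head.  The
package covers the full workflow: strict parsing of affinity tables, the
bounded log-IC50 regression target, a censored loss that uses qualitative
("IC50 > bound") measurements, optional next-token language-model
pretraining on simulated proteasome-cleaved peptide corpora, ensembling,
and an evaluation harness with bootstrap confidence intervals.  Synthetic
generators with known ground truth make every stage testable offline.

## Model in brief

Affinities are regressed on y = 1 − log(IC50)/log(50000), so y = 1 at 1 nM
and y = 0 at the 50 µM cap.  Censored measurements become one-sided
penalties: for "IC50 < b" the model is penalized only for predicting weaker
binding than the bound, for "IC50 > b" only for predicting stronger —
max(0, ·)² in y-space, mean over the batch.  The regressor pools the LSTM
states of the true sequence positions (last ‖ max ‖ mean), never PAD, which
makes predictions exactly padding-invariant.  Training uses Adam under a
1-cycle learning-rate schedule, discriminative per-layer-group rates when
finetuning from pretrained weights, and seed-derived ensembles of 10
models whose y-space predictions are averaged.  Evaluation reports AUC ROC
(binders = IC50 strictly below 500 / 1000 / 100000 nM depending on the
dataset) and Spearman r, aggregated per allele (macro "mean") or pooled
(micro "overall"), with 95% empirical (pivot) bootstrap intervals,
stratified within allele.

See `docs/methods.md` for the full account of the model, training
procedure, synthetic-data design and limitations.

## Worked example

Train on a synthetic benchmark whose ground truth is a hidden per-allele
binding motif (`examples/03_train_and_evaluate.py`):

```bash
$ python examples/03_train_and_evaluate.py
final training loss: 0.0168
held-out AUC ROC    : 0.795 (95% CI 0.719..0.883)
held-out Spearman r : 0.515 (95% CI 0.417..0.631)
```

AUC is the probability that a binder (IC50 < 500 nM) outranks a non-binder
in the predicted scores; Spearman r measures how faithfully the predicted
IC50 ordering tracks the measured one.  The example trains on 1000
peptides to stay fast; at the 2000-peptide scale the verification script
uses, a single from-scratch model reaches Spearman ≈ 0.77-0.91 against the
generator's true energies depending on the hidden motif, and the 10-model
ensemble adds a few points more.  The other examples walk through
the censored loss (`01`), the benchmark generator and its 80%-identity
train/test decontamination (`02`), and language-model pretraining on a
simulated cleavage corpus (`04`).

The same workflow is scriptable from a shell:

```bash
pepmhc make-benchmark --out bench/ --train-size 800 --test-size 200
pepmhc train --data bench/train.csv --allele SYN-A-0000 --ensemble 10 --out model/
pepmhc predict --model model/ --peptides bench/test.csv --out preds.csv
pepmhc evaluate --predictions preds.csv --threshold-nm 500
```

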