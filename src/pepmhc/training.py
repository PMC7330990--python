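"""Training engines: LM pretraining, regressor finetuning, ensembling.

Optimization is Adam with gradient-norm clipping under a 1-cycle schedule:
the learning rate ramps linearly from ``max_lr / start_div`` up to
``max_lr`` over the first ``ramp_frac`` of the steps and anneals linearly to
``max_lr / final_div``, while the momentum term (Adam's beta1) cycles
inversely between 0.95 and 0.85.  During finetuning from pretrained
language-model weights, layer
groups (head / recurrent / embedding) receive discriminatively scaled
learning rates: each group below the head is divided by a further factor
(default 2.6), so the freshly initialized head moves fastest and the
pretrained embedding slowest.

The four tool variants — from-scratch vs LM-pretrained, single model vs
ensemble — share a single code path: pretraining only changes the backbone
initialization, and an ensemble is ``ensemble_size`` independently seeded
runs whose predictions are averaged in y-space.

Everything is deterministic given ``TrainConfig.seed``: model init, batch
shuffling, dropout masks and ensemble member seeds are all derived streams
of one ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import affinity_targets as at
from .evaluation import PredictionSet
from .peptide_data import (
    AffinityRecord, DEFAULT_VOCAB, Vocabulary, pad_batch, tokenize,
)
from .sequence_model import (
    AffinityRegressor, ModelConfig, PeptideLanguageModel,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    ``max_lr`` is the 1-cycle peak learning rate; sensible defaults were
    established once with :func:`lr_range_test` (see the methods note) and
    differ between the LM objective (cross-entropy) and the regression
    objective (censored MSE), so :func:`pretrain_lm` overrides it.
    """

    epochs: int = 200
    batch_size: int = 64
    max_lr: float = 2e-2
    ramp_frac: float = 0.3
    start_div: float = 25.0
    final_div: float = 1e4
    mom_max: float = 0.95
    mom_min: float = 0.85
    discriminative_factor: float = 2.6
    weight_decay: float = 0.01
    seed: int = 0
    ensemble_size: int = 10
    val_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if not 0 < self.ramp_frac < 1:
            raise ValueError("ramp_frac must be in (0, 1)")


@dataclass(frozen=True)
class LMMetrics:
    """Language-model quality on held-out peptides.

    perplexity = exp(mean next-token cross-entropy); accuracy = fraction of
    positions where the argmax prediction equals the true next token.
    """

    perplexity: float
    accuracy: float


def one_cycle(step: int, total_steps: int, cfg: TrainConfig) -> tuple[float, float]:
    """Learning rate and momentum at ``step`` of a 1-cycle schedule."""
    warm = max(1.0, cfg.ramp_frac * total_steps)
    if step < warm:
        t = step / warm
        lr = cfg.max_lr * (1 / cfg.start_div + t * (1 - 1 / cfg.start_div))
        mom = cfg.mom_max + t * (cfg.mom_min - cfg.mom_max)
    else:
        t = (step - warm) / max(1.0, total_steps - warm)
        lr = cfg.max_lr * (1 - t * (1 - 1 / cfg.final_div))
        mom = cfg.mom_min + t * (cfg.mom_max - cfg.mom_min)
    return lr, mom


def hash_split(peptides: Sequence[str], val_fraction: float = 0.1):
    """Deterministic train/validation split by md5 hash of the peptide string.

    Reproducible across runs and platforms without storing split files.
    """
    cut = int(round(1000 * val_fraction))
    train_idx, val_idx = [], []
    for i, p in enumerate(peptides):
        bucket = int(hashlib.md5(p.encode()).hexdigest()[:8], 16) % 1000
        (val_idx if bucket < cut else train_idx).append(i)
    return train_idx, val_idx


def derive_member_seeds(master_seed: int, n: int) -> list[int]:
    """Distinct per-member seeds derived deterministically from one master."""
    state = np.random.SeedSequence(master_seed).generate_state(n)
    return [int(s) % (2**31) for s in state]


def _clip_grads(grads: dict, max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


class _Adam:
    """Adam with per-parameter-group LR multipliers and a cycled beta1.

    The 1-cycle schedule drives both the learning rate and beta1 (the
    momentum analogue); beta2 is fixed.  Gradients are clipped to a global
    norm before the update — recurrent nets are prone to occasional
    exploding gradients.
    """

    def __init__(self, params: dict, group_mult: dict[str, float],
                 beta2: float = 0.99, eps: float = 1e-8,
                 clip_norm: float = 1.0, weight_decay: float = 0.0):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.mult = group_mult
        self.beta2 = beta2
        self.eps = eps
        self.clip_norm = clip_norm
        self.weight_decay = weight_decay
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float, momentum: float) -> None:
        if self.clip_norm:
            _clip_grads(grads, self.clip_norm)
        self.t += 1
        b1, b2 = momentum, self.beta2
        for name, g in grads.items():
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            eff_lr = lr * self.mult.get(name, 1.0)
            if self.weight_decay:
                params[name] *= 1.0 - eff_lr * self.weight_decay
            params[name] -= eff_lr * mhat / (np.sqrt(vhat) + self.eps)


def _group_multipliers(model, discriminative_factor: float | None) -> dict[str, float]:
    mult: dict[str, float] = {}
    factor = 1.0
    for group, names in model.layer_groups.items():  # ordered head -> emb
        for n in names:
            mult[n] = 1.0 / factor
        if discriminative_factor:
            factor *= discriminative_factor
    return mult


# ---------------------------------------------------------------------------
# LR range test
# ---------------------------------------------------------------------------

def suggest_lr_from_curve(lrs: Sequence[float], losses: Sequence[float],
                          smoothing: float = 0.3) -> float:
    """Apply the range-test rule to a recorded loss-vs-LR curve.

    The loss is exponentially smoothed; the divergence point is taken as the
    LR with the minimum smoothed loss (beyond it the loss rises), and the
    suggestion is one order of magnitude below that point.
    """
    if len(lrs) != len(losses) or len(lrs) < 2:
        raise ValueError("need matching lr/loss sequences of length >= 2")
    sm = []
    acc = losses[0]
    for x in losses:
        acc = (1 - smoothing) * acc + smoothing * x
        sm.append(acc)
    best = int(np.argmin(sm))
    return float(lrs[best]) / 10.0


def lr_range_test(model, batches: Sequence[tuple], lr_bounds=(1e-4, 10.0),
                  seed: int = 0) -> float:
    """Sweep the LR exponentially over one pass and suggest a base LR.

    ``batches`` is a list of argument tuples for ``model.loss_and_grads``
    (``(batch,)`` for a language model, ``(batch, y, direction)`` for a
    regressor).  Model parameters are restored afterwards.  Deterministic
    given ``seed``.
    """
    if len(batches) < 2:
        raise ValueError("range test needs at least two batches")
    saved = {k: v.copy() for k, v in model.params.items()}
    rng = np.random.default_rng(seed)
    opt = _Adam(model.params, {})
    lr_lo, lr_hi = lr_bounds
    n = len(batches)
    lrs, losses = [], []
    try:
        for step, args in enumerate(batches):
            lr = lr_lo * (lr_hi / lr_lo) ** (step / (n - 1))
            loss, grads = model.loss_and_grads(*args, train=True, rng=rng)
            if not np.isfinite(loss):
                if step == 0:
                    raise FloatingPointError(
                        "loss not finite at the smallest learning rate; "
                        "data or model misconfigured"
                    )
                break
            lrs.append(lr)
            losses.append(loss)
            if len(losses) > 5 and loss > 10 * losses[0]:
                break
            opt.step(model.params, grads, lr, momentum=0.9)
    finally:
        model.params.update(saved)
    return suggest_lr_from_curve(lrs, losses)


# ---------------------------------------------------------------------------
# Language-model pretraining
# ---------------------------------------------------------------------------

def _lm_batches(encoded, idx, batch_size, rng=None):
    order = np.array(idx)
    if rng is not None:
        rng.shuffle(order)
    for lo in range(0, len(order), batch_size):
        chunk = [encoded[i] for i in order[lo : lo + batch_size]]
        yield pad_batch(chunk)


def evaluate_lm(model: PeptideLanguageModel, peptides: Sequence[str],
                vocab: Vocabulary = DEFAULT_VOCAB,
                batch_size: int = 256) -> LMMetrics:
    """Token-weighted perplexity and next-token accuracy on a peptide set."""
    encoded = [tokenize(p, vocab) for p in peptides]
    ce_sum = 0.0
    correct = 0
    n_tok = 0
    for batch in _lm_batches(encoded, range(len(encoded)), batch_size):
        ce, acc = model.loss_and_metrics(batch)
        n = int((batch.lengths - 1).sum())
        ce_sum += ce * n
        correct += int(round(acc * n))
        n_tok += n
    return LMMetrics(perplexity=float(np.exp(ce_sum / n_tok)),
                     accuracy=correct / n_tok)


def pretrain_lm(corpus: Sequence[str], cfg: ModelConfig,
                tcfg: TrainConfig | None = None,
                vocab: Vocabulary = DEFAULT_VOCAB):
    """Train a next-token language model on a peptide corpus.

    A held-out fraction is split off by deterministic peptide hash and the
    returned :class:`LMMetrics` are computed on it only.  For degenerate
    corpora whose hash split leaves one side empty (e.g. a single repeated
    peptide), the held-out set falls back to the training peptides, with a
    warning.

    Returns ``(model, metrics)``; ``model.params`` holds the backbone
    weights consumed by :func:`finetune_regressor`.
    """
    if tcfg is None:
        tcfg = TrainConfig(epochs=20, max_lr=1e-2, weight_decay=0.3,
                           batch_size=128, val_fraction=0.1)
    if tcfg.val_fraction <= 0:
        # LM metrics are only meaningful on held-out peptides
        logger.info("pretrain_lm requires a held-out split; using 10%%")
        tcfg = replace(tcfg, val_fraction=0.1)
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    if len(corpus) < tcfg.batch_size:
        logger.info("corpus smaller than one batch (%d < %d); batching whole "
                    "corpus", len(corpus), tcfg.batch_size)

    train_idx, val_idx = hash_split(corpus, tcfg.val_fraction)
    if not train_idx or not val_idx:
        logger.warning("degenerate corpus: hash split left one side empty; "
                       "evaluating held-out metrics on the training peptides")
        train_idx = list(range(len(corpus)))
        val_idx = list(range(len(corpus)))

    encoded = [tokenize(p, vocab) for p in corpus]
    ss = np.random.SeedSequence(tcfg.seed)
    init_ss, shuffle_ss, drop_ss = ss.spawn(3)
    model = PeptideLanguageModel(cfg, seed=init_ss)
    shuffle_rng = np.random.default_rng(shuffle_ss)
    drop_rng = np.random.default_rng(drop_ss)

    steps_per_epoch = max(1, int(np.ceil(len(train_idx) / tcfg.batch_size)))
    total_steps = steps_per_epoch * tcfg.epochs
    opt = _Adam(model.params, {}, weight_decay=tcfg.weight_decay)
    step = 0
    for _ in range(tcfg.epochs):
        for batch in _lm_batches(encoded, train_idx, tcfg.batch_size, shuffle_rng):
            lr, mom = one_cycle(step, total_steps, tcfg)
            _, grads = model.loss_and_grads(batch, train=True, rng=drop_rng)
            opt.step(model.params, grads, lr, mom)
            step += 1
    metrics = evaluate_lm(model, [corpus[i] for i in val_idx], vocab)
    logger.info("LM pretraining done: perplexity %.3f accuracy %.3f",
                metrics.perplexity, metrics.accuracy)
    return model, metrics


# ---------------------------------------------------------------------------
# Regression finetuning
# ---------------------------------------------------------------------------

@dataclass
class RegressorPredictor:
    """A trained per-allele predictor with its training history."""

    model: AffinityRegressor
    allele_id: str
    cap_nm: float
    vocab: Vocabulary
    history: dict = field(default_factory=dict)

    def predict_y(self, peptides: Sequence[str]) -> np.ndarray:
        encoded = [tokenize(p, self.vocab) for p in peptides]
        out = np.empty(len(peptides))
        for lo in range(0, len(encoded), 256):
            chunk = encoded[lo : lo + 256]
            out[lo : lo + len(chunk)] = self.model.predict(pad_batch(chunk))
        return out


@dataclass
class EnsemblePredictor:
    """Averages member predictions in y-space."""

    members: list[RegressorPredictor]

    @property
    def allele_id(self) -> str:
        return self.members[0].allele_id

    @property
    def cap_nm(self) -> float:
        return self.members[0].cap_nm

    def predict_y(self, peptides: Sequence[str]) -> np.ndarray:
        return np.mean([m.predict_y(peptides) for m in self.members], axis=0)


def _prepare_regression_data(records, cap_nm, vocab):
    peptides = [r.peptide for r in records]
    encoded = [tokenize(p, vocab) for p in peptides]
    targets = [at.record_to_target(r, cap_nm) for r in records]
    y = np.array([t.y for t in targets])
    direction = np.array([int(t.direction) for t in targets])
    return peptides, encoded, y, direction


def finetune_regressor(records: Sequence[AffinityRecord], cfg: ModelConfig,
                       tcfg: TrainConfig,
                       pretrained: dict[str, np.ndarray] | None = None,
                       cap_nm: float = at.DEFAULT_CAP_NM,
                       vocab: Vocabulary = DEFAULT_VOCAB) -> RegressorPredictor:
    """Train one per-allele affinity regressor under the censored MSE loss.

    All records must share one allele (one predictor per allele).  When
    ``pretrained`` backbone weights are supplied, discriminative learning
    rates scale the updates of the recurrent and embedding groups down by
    ``tcfg.discriminative_factor`` per group below the head.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    alleles = {r.allele_id for r in records}
    if len(alleles) != 1:
        raise ValueError(
            f"finetune_regressor trains one allele at a time, got {sorted(alleles)}"
        )

    peptides, encoded, y, direction = _prepare_regression_data(records, cap_nm, vocab)
    train_idx, val_idx = hash_split(peptides, tcfg.val_fraction)
    if not train_idx:
        train_idx = list(range(len(records)))
        val_idx = []

    ss = np.random.SeedSequence(tcfg.seed)
    init_ss, shuffle_ss, drop_ss = ss.spawn(3)
    model = AffinityRegressor(cfg, seed=init_ss, pretrained=pretrained)
    shuffle_rng = np.random.default_rng(shuffle_ss)
    drop_rng = np.random.default_rng(drop_ss)

    mult = _group_multipliers(
        model, tcfg.discriminative_factor if pretrained is not None else None
    )
    opt = _Adam(model.params, mult, weight_decay=tcfg.weight_decay)

    steps_per_epoch = max(1, int(np.ceil(len(train_idx) / tcfg.batch_size)))
    total_steps = steps_per_epoch * tcfg.epochs
    history: dict = {"train_loss": [], "val_spearman": []}
    step = 0
    order = np.array(train_idx)
    for _ in range(tcfg.epochs):
        shuffle_rng.shuffle(order)
        epoch_loss = 0.0
        nb = 0
        for lo in range(0, len(order), tcfg.batch_size):
            sel = order[lo : lo + tcfg.batch_size]
            batch = pad_batch([encoded[i] for i in sel])
            lr, mom = one_cycle(step, total_steps, tcfg)
            loss, grads = model.loss_and_grads(
                batch, y[sel], direction[sel], train=True, rng=drop_rng
            )
            opt.step(model.params, grads, lr, mom)
            epoch_loss += loss
            nb += 1
            step += 1
        history["train_loss"].append(epoch_loss / nb)

    predictor = RegressorPredictor(
        model=model, allele_id=records[0].allele_id, cap_nm=cap_nm,
        vocab=vocab, history=history,
    )
    if val_idx:
        from scipy.stats import spearmanr

        quant = [i for i in val_idx if direction[i] == at.BoundDirection.POINT]
        if len(quant) >= 3:
            yp = predictor.predict_y([peptides[i] for i in quant])
            rho = spearmanr(y[quant], yp).statistic
            history["val_spearman"].append(float(rho))
    return predictor


def train_ensemble(records: Sequence[AffinityRecord], cfg: ModelConfig,
                   tcfg: TrainConfig,
                   pretrained: dict[str, np.ndarray] | None = None,
                   cap_nm: float = at.DEFAULT_CAP_NM,
                   vocab: Vocabulary = DEFAULT_VOCAB) -> EnsemblePredictor:
    """Train ``tcfg.ensemble_size`` members with distinct derived seeds."""
    seeds = derive_member_seeds(tcfg.seed, tcfg.ensemble_size)
    members = [
        finetune_regressor(records, cfg, replace(tcfg, seed=s),
                           pretrained=pretrained, cap_nm=cap_nm, vocab=vocab)
        for s in seeds
    ]
    return EnsemblePredictor(members=members)


def predict(handle, peptides) -> PredictionSet:
    """Predict y and IC50 for every input peptide; no silent drops.

    ``peptides`` may be plain strings or :class:`AffinityRecord` instances;
    records carry their measured values into the output for evaluation.
    """
    if len(peptides) and isinstance(peptides[0], AffinityRecord):
        records = list(peptides)
        seqs = [r.peptide for r in records]
    else:
        records = None
        seqs = list(peptides)
    y_pred = handle.predict_y(seqs)
    if records is not None:
        return PredictionSet.from_records(records, y_pred, cap_nm=handle.cap_nm)
    return PredictionSet.from_peptides(
        handle.allele_id, seqs, y_pred, cap_nm=handle.cap_nm
    )
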