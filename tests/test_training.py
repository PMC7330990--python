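"""Training engines: schedules, LR range test, reproducibility, ensembling."""

import numpy as np
import pytest

from pepmhc.affinity_targets import target_to_ic50
from pepmhc.peptide_data import AMINO_ACIDS, AffinityRecord
from pepmhc.sequence_model import ModelConfig
from pepmhc.training import (
    TrainConfig, derive_member_seeds, evaluate_lm, finetune_regressor,
    hash_split, lr_range_test, one_cycle, predict, pretrain_lm,
    suggest_lr_from_curve, train_ensemble,
)

# small architecture keeps the unit tests fast; defaults are exercised in
# the acceptance suite
SMALL = ModelConfig(embedding_dim=12, hidden_units=16, head_hidden=8)
FAST = dict(epochs=100, batch_size=32, max_lr=2e-2)


def _position_task_records(rng, n=240, pos=8, allele="SYN-T-0001"):
    """Peptides whose affinity is a deterministic function of one residue.

    The C-terminal position mirrors the canonical class I anchor residue.
    """
    aa = np.array(list(AMINO_ACIDS))
    records = []
    for _ in range(n):
        pep = "".join(aa[rng.integers(0, 20, size=9)])
        y = 0.1 + 0.8 * (AMINO_ACIDS.index(pep[pos]) / 19.0)
        records.append(AffinityRecord(allele, pep, target_to_ic50(y)))
    return records


class TestOneCycle:
    cfg = TrainConfig()

    def test_starts_low_peaks_at_ramp_end(self):
        lr0, mom0 = one_cycle(0, 1000, self.cfg)
        lr_peak, mom_peak = one_cycle(300, 1000, self.cfg)
        assert lr0 == pytest.approx(self.cfg.max_lr / self.cfg.start_div)
        assert lr_peak == pytest.approx(self.cfg.max_lr)
        assert mom0 == self.cfg.mom_max and mom_peak == self.cfg.mom_min

    def test_final_lr_tiny_momentum_recovers(self):
        lr_end, mom_end = one_cycle(1000, 1000, self.cfg)
        assert lr_end <= self.cfg.max_lr / self.cfg.final_div * 1.01
        assert mom_end == pytest.approx(self.cfg.mom_max)


class TestHashSplit:
    def test_deterministic_and_disjoint(self, rng):
        from conftest import random_peptide

        peps = [random_peptide(rng, 9) for _ in range(500)]
        a = hash_split(peps, 0.1)
        b = hash_split(peps, 0.1)
        assert a == b
        assert set(a[0]).isdisjoint(a[1])
        assert len(a[1]) == pytest.approx(50, abs=25)

    def test_split_follows_peptide_not_position(self):
        tr, va = hash_split(["ACDEFGHIK"] * 3, 0.5)
        assert tr == [] or va == []  # identical peptides land together


class TestLrSuggestion:
    def test_convex_curve_suggests_decade_below_minimum(self):
        lrs = np.logspace(-4, 0, 50)
        losses = (np.log10(lrs) + 2.0) ** 2 + 1.0  # minimum at 1e-2
        sug = suggest_lr_from_curve(lrs, losses, smoothing=1.0)
        assert sug == pytest.approx(1e-3, rel=0.3)

    def test_monotone_diverging_curve_suggests_below_range(self):
        lrs = np.logspace(-4, 0, 30)
        losses = np.linspace(1.0, 50.0, 30)
        assert suggest_lr_from_curve(lrs, losses, smoothing=1.0) < lrs.min()

    def test_range_test_deterministic_and_restores_params(self, rng):
        recs = _position_task_records(rng, n=96)
        from pepmhc.training import _prepare_regression_data
        from pepmhc.peptide_data import DEFAULT_VOCAB, pad_batch
        from pepmhc.sequence_model import AffinityRegressor

        _, enc, y, d = _prepare_regression_data(recs, 50000.0, DEFAULT_VOCAB)
        batches = [(pad_batch(enc[i:i + 32]), y[i:i + 32], d[i:i + 32])
                   for i in range(0, 96, 32)] * 3
        model = AffinityRegressor(SMALL, seed=0)
        before = {k: v.copy() for k, v in model.params.items()}
        s1 = lr_range_test(model, batches, seed=3)
        for k in before:
            np.testing.assert_array_equal(model.params[k], before[k])
        assert s1 == lr_range_test(model, batches, seed=3)


class TestPretrainLM:
    def test_degenerate_corpus_perfectly_predictable(self):
        corpus = ["AAAAAAAAA"] * 64
        _, metrics = pretrain_lm(
            corpus, SMALL, TrainConfig(epochs=30, batch_size=32, max_lr=3e-2,
                                       seed=0))
        assert metrics.accuracy == pytest.approx(1.0)
        assert metrics.perplexity == pytest.approx(1.0, abs=0.05)

    def test_untrained_model_near_chance_on_uniform_corpus(self, rng):
        from conftest import random_peptide
        from pepmhc.sequence_model import PeptideLanguageModel

        lm = PeptideLanguageModel(SMALL, seed=1)
        corpus = [random_peptide(rng, 10) for _ in range(300)]
        metrics = evaluate_lm(lm, corpus)
        assert metrics.accuracy == pytest.approx(1 / 20, abs=0.04)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            pretrain_lm([], SMALL, TrainConfig())


class TestFinetune:
    def test_single_position_task_learnable(self, rng):
        records = _position_task_records(rng)
        tcfg = TrainConfig(seed=2, **FAST)
        h = finetune_regressor(records, SMALL, tcfg)
        held = _position_task_records(np.random.default_rng(777), n=80)
        y_pred = h.predict_y([r.peptide for r in held])
        y_true = [0.1 + 0.8 * (AMINO_ACIDS.index(r.peptide[8]) / 19.0)
                  for r in held]
        from scipy.stats import spearmanr

        assert spearmanr(y_pred, y_true).statistic >= 0.95

    def test_same_seed_bit_identical_predictions(self, rng):
        records = _position_task_records(rng, n=64)
        tcfg = TrainConfig(seed=5, epochs=6, batch_size=32, max_lr=2e-2)
        h1 = finetune_regressor(records, SMALL, tcfg)
        h2 = finetune_regressor(records, SMALL, tcfg)
        peps = [r.peptide for r in records[:10]]
        np.testing.assert_array_equal(h1.predict_y(peps), h2.predict_y(peps))

    def test_feasible_censoring_drives_loss_to_zero(self, rng):
        from conftest import random_peptide
        from pepmhc.peptide_data import Inequality, MeasurementKind

        records = [AffinityRecord("A", random_peptide(rng, 9), 50000.0,
                                  Inequality.GT, MeasurementKind.qualitative)
                   for _ in range(64)]
        h = finetune_regressor(records, SMALL,
                               TrainConfig(seed=1, epochs=30, batch_size=32,
                                           max_lr=2e-2))
        assert h.history["train_loss"][-1] < 1e-4

    def test_mixed_alleles_rejected(self, rng):
        records = (_position_task_records(rng, n=4, allele="A") +
                   _position_task_records(rng, n=4, allele="B"))
        with pytest.raises(ValueError, match="one allele"):
            finetune_regressor(records, SMALL, TrainConfig())

    def test_too_few_records_rejected(self, rng):
        with pytest.raises(ValueError):
            finetune_regressor(_position_task_records(rng, n=1), SMALL,
                               TrainConfig())


class TestEnsemble:
    def test_member_seeds_distinct_and_deterministic(self):
        s1 = derive_member_seeds(42, 10)
        assert s1 == derive_member_seeds(42, 10)
        assert len(set(s1)) == 10
        assert all(0 <= s < 2**31 for s in s1)

    def test_ensemble_of_one_equals_single_model(self, rng):
        records = _position_task_records(rng, n=64)
        tcfg = TrainConfig(seed=9, epochs=6, batch_size=32, max_lr=2e-2,
                           ensemble_size=1)
        ens = train_ensemble(records, SMALL, tcfg)
        from dataclasses import replace

        member_seed = derive_member_seeds(9, 1)[0]
        sng = finetune_regressor(records, SMALL,
                                 replace(tcfg, seed=member_seed))
        peps = [r.peptide for r in records[:12]]
        np.testing.assert_array_equal(ens.predict_y(peps),
                                      sng.predict_y(peps))

    def test_prediction_is_member_mean(self, rng):
        records = _position_task_records(rng, n=64)
        tcfg = TrainConfig(seed=4, epochs=6, batch_size=32, max_lr=2e-2,
                           ensemble_size=2)
        ens = train_ensemble(records, SMALL, tcfg)
        peps = [r.peptide for r in records[:8]]
        want = np.mean([m.predict_y(peps) for m in ens.members], axis=0)
        np.testing.assert_allclose(ens.predict_y(peps), want, atol=1e-12)


class TestPredict:
    def _handle(self, rng):
        records = _position_task_records(rng, n=64)
        return finetune_regressor(
            records, SMALL, TrainConfig(seed=3, epochs=6, batch_size=32,
                                        max_lr=2e-2)), records

    def test_row_per_input_and_consistency(self, rng):
        h, records = self._handle(rng)
        peps = [r.peptide for r in records[:20]]
        pred = predict(h, peps)
        assert len(pred) == 20
        got = pred.frame["predicted_ic50_nM"].to_numpy()
        want = target_to_ic50(pred.frame["y_pred"].to_numpy())
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_batched_equals_one_at_a_time(self, rng):
        h, records = self._handle(rng)
        peps = [r.peptide for r in records[:15]]
        together = h.predict_y(peps)
        alone = np.array([h.predict_y([p])[0] for p in peps])
        np.testing.assert_allclose(together, alone, atol=1e-6)

    def test_records_carry_truth_into_prediction_set(self, rng):
        h, records = self._handle(rng)
        pred = predict(h, records[:5])
        assert list(pred.frame["measured_ic50_nM"]) == \
            [r.ic50_nm for r in records[:5]]
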