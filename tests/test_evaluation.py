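"""Metrics, aggregation, bootstrap CIs and the train/test similarity audit."""

import numpy as np
import pandas as pd
import pytest

from pepmhc.affinity_targets import BinderThreshold, ic50_to_target
from pepmhc.evaluation import (
    PredictionSet, aggregate, auc_roc, bootstrap_ci, metric_overall_auc,
    multi_run_report, similarity_overlap_audit, spearman_r,
)
from pepmhc.peptide_data import AffinityRecord


def pairwise_auc_oracle(labels, scores):
    """O(n^2) Mann-Whitney pair counting."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def midrank(v):
    """Average ranks on ties, 1-based."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    rx, ry = midrank(x), midrank(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def make_predset(alleles, ic50s, y_preds, kinds=None, ineqs=None):
    n = len(alleles)
    kinds = kinds or ["quant"] * n
    ineqs = ineqs or ["="] * n
    y_true = ic50_to_target(np.asarray(ic50s, dtype=float))
    return PredictionSet(pd.DataFrame({
        "allele": alleles,
        "peptide": [f"ACDEFGHKL" for _ in range(n)],
        "measured_ic50_nM": ic50s,
        "inequality": ineqs,
        "kind": kinds,
        "y_true": y_true,
        "y_pred": y_preds,
        "predicted_ic50_nM": 50000.0 ** (1 - np.clip(y_preds, 0, 1)),
    }))


class TestAucRoc:
    def test_perfect_ranking(self):
        assert auc_roc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_all_ties_give_half(self):
        assert auc_roc([1, 0, 1, 0], [0.5] * 4) == pytest.approx(0.5)

    def test_single_class_undefined(self):
        assert auc_roc([1, 1, 1], [0.1, 0.2, 0.3]) is None

    def test_matches_pair_count_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 60))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.normal(size=n), 1)  # provoke ties
            assert auc_roc(labels, scores) == pytest.approx(
                pairwise_auc_oracle(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        scores = rng.normal(size=50)
        a1 = auc_roc(labels, scores)
        a2 = auc_roc(labels, np.exp(3 * scores) + 7)
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestSpearman:
    def test_linear_is_one(self):
        x = np.arange(10.0)
        assert spearman_r(x, 2 * x + 1) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        x = np.arange(10.0)
        assert spearman_r(x, -x) == pytest.approx(-1.0)

    def test_constant_undefined(self):
        assert spearman_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) is None

    def test_tied_example_matches_midrank_oracle(self):
        x, y = [1, 2, 2, 4], [3, 1, 2, 4]
        assert spearman_r(x, y) == pytest.approx(spearman_oracle(x, y),
                                                 abs=1e-12)

    def test_matches_oracle_random(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 40))
            x = np.round(rng.normal(size=n), 1)
            y = np.round(rng.normal(size=n), 1)
            got = spearman_r(x, y)
            if got is not None:
                assert got == pytest.approx(spearman_oracle(x, y), abs=1e-12)


class TestAggregate:
    thr = BinderThreshold(500.0)

    def test_single_allele_mean_equals_overall(self, rng):
        n = 40
        ic50 = rng.uniform(10, 40000, size=n)
        pred = make_predset(["A"] * n, ic50, rng.normal(size=n))
        rep = aggregate(pred, self.thr)
        assert rep.mean_auc == rep.overall_auc
        assert rep.mean_spearman == rep.overall_spearman

    def test_two_allele_size_imbalance(self, rng):
        # allele A: perfect AUC on 10 rows; allele B: coin-flip AUC on 1000
        a_ic50 = [100.0] * 5 + [10000.0] * 5
        a_pred = [0.9] * 5 + [0.1] * 5
        b_lab = rng.integers(0, 2, size=1000)
        b_ic50 = np.where(b_lab, 100.0, 10000.0)
        b_pred = rng.normal(size=1000)
        pred = make_predset(["A"] * 10 + ["B"] * 1000,
                            np.concatenate([a_ic50, b_ic50]),
                            np.concatenate([a_pred, b_pred]))
        rep = aggregate(pred, self.thr)
        auc_b = [m.auc for m in rep.per_allele if m.allele == "B"][0]
        assert rep.mean_auc == pytest.approx((1.0 + auc_b) / 2)
        # overall is dominated by the big allele: verify with the pair oracle
        labels = pred.binder_labels(self.thr)
        oracle = pairwise_auc_oracle(labels, pred.frame["y_pred"].to_numpy())
        assert rep.overall_auc == pytest.approx(oracle, abs=1e-12)
        assert abs(rep.overall_auc - auc_b) < 0.1

    def test_single_class_allele_excluded_from_mean_but_pooled(self, rng):
        n = 30
        ic50 = list(rng.uniform(10, 40000, size=n)) + [100.0] * 5
        preds = list(rng.normal(size=n)) + [0.5] * 5
        pred = make_predset(["A"] * n + ["ONLYPOS"] * 5, ic50, preds)
        rep = aggregate(pred, self.thr)
        assert "ONLYPOS" in rep.excluded_auc
        per_a = [m.auc for m in rep.per_allele if m.allele == "A"][0]
        assert rep.mean_auc == per_a
        labels = pred.binder_labels(self.thr)
        assert rep.overall_auc == pytest.approx(
            pairwise_auc_oracle(labels, pred.frame["y_pred"].to_numpy()))

    def test_mean_invariant_to_duplication_overall_not(self, rng):
        ic50 = np.concatenate([rng.uniform(10, 40000, size=30),
                               rng.uniform(10, 40000, size=30)])
        preds = np.concatenate([ic50[:30] * -1e-5 + rng.normal(size=30),
                                rng.normal(size=30)])
        alleles = ["A"] * 30 + ["B"] * 30
        pred = make_predset(alleles, ic50, preds)
        dup = PredictionSet(pd.concat(
            [pred.frame, pred.frame[pred.frame.allele == "B"]],
            ignore_index=True))
        r1, r2 = aggregate(pred, self.thr), aggregate(dup, self.thr)
        assert r1.mean_auc == pytest.approx(r2.mean_auc, abs=1e-12)
        assert r1.overall_auc != pytest.approx(r2.overall_auc, abs=1e-6)


class TestBootstrap:
    thr = BinderThreshold(500.0)

    def test_separable_data_zero_width(self, rng):
        # AUC is 1 under every resample: the interval collapses
        ic50 = [100.0] * 20 + [10000.0] * 20
        preds = [1.0 + i * 1e-3 for i in range(20)] + \
                [0.0 - i * 1e-3 for i in range(20)]
        pred = make_predset(["A"] * 40, ic50, preds)
        lo, hi = bootstrap_ci(metric_overall_auc(self.thr), pred, B=200, seed=0)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_interval_contains_point_estimate(self, rng):
        n = 200
        lab = rng.integers(0, 2, size=n)
        ic50 = np.where(lab, 100.0, 10000.0)
        preds = lab + rng.normal(scale=1.0, size=n)
        pred = make_predset(["A"] * n, ic50, preds)
        fn = metric_overall_auc(self.thr)
        theta = fn(pred)
        lo, hi = bootstrap_ci(fn, pred, B=300, seed=1)
        assert lo <= theta <= hi

    def test_deterministic_given_seed(self, rng):
        n = 60
        lab = rng.integers(0, 2, size=n)
        pred = make_predset(["A"] * n, np.where(lab, 100.0, 10000.0),
                            lab + rng.normal(size=n))
        fn = metric_overall_auc(self.thr)
        assert bootstrap_ci(fn, pred, B=150, seed=7) == \
            bootstrap_ci(fn, pred, B=150, seed=7)

    def test_width_shrinks_with_n(self, rng):
        fn = metric_overall_auc(self.thr)
        widths = []
        for n in (100, 400, 1600):
            lab = rng.integers(0, 2, size=n)
            pred = make_predset(["A"] * n, np.where(lab, 100.0, 10000.0),
                                lab + rng.normal(size=n))
            lo, hi = bootstrap_ci(fn, pred, B=200, seed=2)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_small_B_rejected(self, rng):
        pred = make_predset(["A"] * 4, [100.0, 100.0, 10000.0, 10000.0],
                            [0.9, 0.8, 0.1, 0.2])
        with pytest.raises(ValueError):
            bootstrap_ci(metric_overall_auc(self.thr), pred, B=10, seed=0)


class TestMultiRunReport:
    def test_identical_runs(self):
        mean, err = multi_run_report([0.8, 0.8], [(0.78, 0.82), (0.78, 0.82)])
        assert mean == pytest.approx(0.8)
        assert err == pytest.approx(0.02)

    def test_conservative_rule_example(self):
        mean, err = multi_run_report([0.80, 0.82], [(0.78, 0.83), (0.80, 0.83)])
        assert mean == pytest.approx(0.81)
        assert err == pytest.approx(0.03)

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            multi_run_report([0.8], [(0.7, 0.9)])


class TestSimilarityAudit:
    def test_identical_peptides_flagged(self):
        out = similarity_overlap_audit(["ACDEFGHIK"], ["ACDEFGHIK"], 0.8)
        assert list(out["peptide"]) == ["ACDEFGHIK"]
        assert out["identity"].iloc[0] == 1.0

    def test_seven_of_nine_not_flagged(self):
        out = similarity_overlap_audit(["ACDEFGHIK"], ["ACDEFGHYW"], 0.8)
        assert len(out) == 0  # 7/9 ~ 0.778 < 0.8

    def test_eight_of_nine_flagged(self):
        out = similarity_overlap_audit(["ACDEFGHIK"], ["ACDEFGHIW"], 0.8)
        assert len(out) == 1
        assert out["identity"].iloc[0] == pytest.approx(8 / 9)

    def test_different_lengths_never_compared(self):
        out = similarity_overlap_audit(["ACDEFGHIK"], ["ACDEFGHIKL"], 0.1)
        assert len(out) == 0

    def test_accepts_records(self):
        train = [AffinityRecord("A", "ACDEFGHIK", 10.0)]
        test = [AffinityRecord("A", "ACDEFGHIK", 10.0)]
        assert len(similarity_overlap_audit(train, test, 0.8)) == 1
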