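"""Evaluation harness: AUC ROC, Spearman r, aggregation, bootstrap CIs.

Two aggregation modes are supported for multi-allele benchmarks:

* ``mean`` (macro): the unweighted average of per-allele metrics, giving
  every allele's test set equal weight;
* ``overall`` (micro): the metric computed on all predictions pooled
  across alleles, which weights alleles by test-set size and implicitly
  assumes scores are comparable between alleles.

Per-allele metrics can be *undefined* — AUC needs both classes present,
Spearman needs at least two quantitative measurements with rank variance —
and undefined alleles are excluded from the ``mean`` aggregate (and
reported), while their rows still enter the pooled ``overall`` computation
whenever that metric is defined on the pool.

Confidence intervals are 95% empirical (basic / reverse-percentile)
bootstrap intervals, resampling rows with replacement stratified within
allele so the allele composition of the benchmark is preserved.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.stats import spearmanr as _scipy_spearmanr

from . import affinity_targets as at
from .peptide_data import AffinityRecord, Inequality, MeasurementKind

logger = logging.getLogger(__name__)

#: Spearman is reported per allele only above this many quantitative points.
DEFAULT_MIN_QUANT = 25


# ---------------------------------------------------------------------------
# Prediction container
# ---------------------------------------------------------------------------

@dataclass
class PredictionSet:
    """Per-peptide predictions paired with measured targets.

    Backed by a DataFrame with columns ``allele``, ``peptide``,
    ``measured_ic50_nM``, ``inequality``, ``kind``, ``y_true``, ``y_pred``,
    ``predicted_ic50_nM``.  Measured fields are NaN/empty for peptides
    predicted without a ground-truth record.
    """

    frame: pd.DataFrame

    COLUMNS = ("allele", "peptide", "measured_ic50_nM", "inequality", "kind",
               "y_true", "y_pred", "predicted_ic50_nM")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"PredictionSet missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_records(cls, records: Sequence[AffinityRecord],
                     y_pred: np.ndarray,
                     cap_nm: float = at.DEFAULT_CAP_NM) -> "PredictionSet":
        if len(records) != len(y_pred):
            raise ValueError("records and predictions differ in length")
        df = pd.DataFrame({
            "allele": [r.allele_id for r in records],
            "peptide": [r.peptide for r in records],
            "measured_ic50_nM": [r.ic50_nm for r in records],
            "inequality": [r.inequality.value for r in records],
            "kind": [r.kind.value for r in records],
            "y_true": at.ic50_to_target([r.ic50_nm for r in records], cap_nm),
            "y_pred": np.asarray(y_pred, dtype=float),
            "predicted_ic50_nM": at.target_to_ic50(
                np.asarray(y_pred, dtype=float), cap_nm),
        })
        return cls(df)

    @classmethod
    def from_peptides(cls, allele_id: str, peptides: Sequence[str],
                      y_pred: np.ndarray,
                      cap_nm: float = at.DEFAULT_CAP_NM) -> "PredictionSet":
        y_pred = np.asarray(y_pred, dtype=float)
        df = pd.DataFrame({
            "allele": allele_id,
            "peptide": list(peptides),
            "measured_ic50_nM": np.nan,
            "inequality": "",
            "kind": "",
            "y_true": np.nan,
            "y_pred": y_pred,
            "predicted_ic50_nM": at.target_to_ic50(y_pred, cap_nm),
        })
        return cls(df)

    def binder_labels(self, thr: at.BinderThreshold) -> np.ndarray:
        """0/1 labels from measured IC50 values (bound value for censored rows)."""
        return at.binder_label(self.frame["measured_ic50_nM"].to_numpy(), thr)

    def concat(self, other: "PredictionSet") -> "PredictionSet":
        return PredictionSet(
            pd.concat([self.frame, other.frame], ignore_index=True)
        )

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "PredictionSet":
        return cls(pd.read_csv(path, keep_default_na=True,
                               dtype={"inequality": str, "kind": str}))


# ---------------------------------------------------------------------------
# Core metrics
# ---------------------------------------------------------------------------

def auc_roc(labels, scores) -> float | None:
    """Area under the ROC curve; the Mann-Whitney probability of correct
    pairwise ranking, with ties counting one half.

    Computed through the rank-sum identity on average ranks, which equals
    the trapezoidal ROC area exactly and stays cheap inside bootstrap
    loops.  Returns ``None`` (undefined) when only one class is present, so
    callers can apply the exclusion rules rather than crash at aggregate
    level.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def spearman_r(x, y) -> float | None:
    """Spearman rank correlation (Pearson on mid-ranks; average-rank ties).

    Returns ``None`` when undefined (fewer than 2 pairs, or a constant
    vector with zero rank variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = _scipy_spearmanr(x, y).statistic
    return None if np.isnan(rho) else float(rho)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

@dataclass
class AlleleMetrics:
    allele: str
    n: int
    n_quant: int
    auc: float | None
    spearman: float | None
    spearman_reported: bool = True  # False when n_quant below the report floor


@dataclass
class MetricReport:
    """Per-allele and aggregate AUC / Spearman with exclusion bookkeeping."""

    per_allele: list[AlleleMetrics]
    mean_auc: float | None
    mean_spearman: float | None
    overall_auc: float | None
    overall_spearman: float | None
    excluded_auc: list[str] = field(default_factory=list)
    excluded_spearman: list[str] = field(default_factory=list)
    ci: dict = field(default_factory=dict)
    B: int | None = None
    seed: int | None = None
    level: float = 0.95

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "per_allele": [vars(a) for a in self.per_allele],
            "aggregates": {
                "mean_auc": self.mean_auc,
                "mean_spearman": self.mean_spearman,
                "overall_auc": self.overall_auc,
                "overall_spearman": self.overall_spearman,
            },
            "excluded": {"auc": self.excluded_auc,
                         "spearman": self.excluded_spearman},
            "ci": self.ci, "B": self.B, "seed": self.seed, "level": self.level,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_text(self) -> str:
        lines = [f"{'allele':<16}{'n':>6}{'n_quant':>9}{'AUC':>8}{'Spearman':>10}"]
        for a in self.per_allele:
            auc = "--" if a.auc is None else f"{a.auc:.3f}"
            rho = "--" if (a.spearman is None or not a.spearman_reported) \
                else f"{a.spearman:.3f}"
            lines.append(f"{a.allele:<16}{a.n:>6}{a.n_quant:>9}{auc:>8}{rho:>10}")
        for name in ("mean_auc", "mean_spearman", "overall_auc",
                     "overall_spearman"):
            v = getattr(self, name)
            lines.append(f"{name:<31}{'--' if v is None else f'{v:.4f}':>8}")
        return "\n".join(lines)


def _quant_mask(frame: pd.DataFrame) -> np.ndarray:
    return (frame["kind"].to_numpy() == MeasurementKind.quantitative.value) & (
        frame["inequality"].to_numpy() == Inequality.EQ.value
    )


def allele_metrics(pred: PredictionSet, thr: at.BinderThreshold,
                   min_quant: int = DEFAULT_MIN_QUANT) -> list[AlleleMetrics]:
    """Per-allele AUC (all rows via binder labels) and Spearman (EQ rows only)."""
    out = []
    labels = pred.binder_labels(thr)
    quant = _quant_mask(pred.frame)
    for allele, grp in pred.frame.groupby("allele", sort=True):
        idx = grp.index.to_numpy()
        q = idx[quant[idx]]
        rho = spearman_r(pred.frame.loc[q, "y_true"].to_numpy(),
                         pred.frame.loc[q, "y_pred"].to_numpy()) \
            if len(q) >= 2 else None
        out.append(AlleleMetrics(
            allele=allele, n=len(idx), n_quant=len(q),
            auc=auc_roc(labels[idx], pred.frame.loc[idx, "y_pred"].to_numpy()),
            spearman=rho,
            spearman_reported=len(q) > min_quant,
        ))
    return out


def aggregate(pred: PredictionSet, thr: at.BinderThreshold,
              min_quant: int = DEFAULT_MIN_QUANT) -> MetricReport:
    """Compute per-allele, mean (macro) and overall (micro) AUC and Spearman.

    Alleles whose metric is undefined are excluded from the mean aggregate
    and listed; all rows still enter the pooled overall computation.
    """
    if len(pred) == 0:
        raise ValueError("empty prediction set")
    per = allele_metrics(pred, thr, min_quant)
    aucs = [a.auc for a in per if a.auc is not None]
    rhos = [a.spearman for a in per if a.spearman is not None]
    labels = pred.binder_labels(thr)
    quant = _quant_mask(pred.frame)
    return MetricReport(
        per_allele=per,
        mean_auc=float(np.mean(aucs)) if aucs else None,
        mean_spearman=float(np.mean(rhos)) if rhos else None,
        overall_auc=auc_roc(labels, pred.frame["y_pred"].to_numpy()),
        overall_spearman=spearman_r(
            pred.frame.loc[quant, "y_true"].to_numpy(),
            pred.frame.loc[quant, "y_pred"].to_numpy(),
        ),
        excluded_auc=[a.allele for a in per if a.auc is None],
        excluded_spearman=[a.allele for a in per if a.spearman is None],
    )


# Convenience metric functions for bootstrap_ci ------------------------------

def metric_overall_auc(thr: at.BinderThreshold) -> Callable[[PredictionSet], float | None]:
    def fn(p: PredictionSet):
        return auc_roc(p.binder_labels(thr), p.frame["y_pred"].to_numpy())
    return fn


def metric_overall_spearman() -> Callable[[PredictionSet], float | None]:
    def fn(p: PredictionSet):
        q = _quant_mask(p.frame)
        return spearman_r(p.frame.loc[q, "y_true"].to_numpy(),
                          p.frame.loc[q, "y_pred"].to_numpy())
    return fn


def metric_mean_auc(thr: at.BinderThreshold) -> Callable[[PredictionSet], float | None]:
    def fn(p: PredictionSet):
        vals = [a.auc for a in allele_metrics(p, thr) if a.auc is not None]
        return float(np.mean(vals)) if vals else None
    return fn


def metric_mean_spearman() -> Callable[[PredictionSet], float | None]:
    def fn(p: PredictionSet):
        vals = [a.spearman for a in allele_metrics(p, at.BinderThreshold())
                if a.spearman is not None]
        return float(np.mean(vals)) if vals else None
    return fn


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(metric: Callable[[PredictionSet], float | None],
                 pred: PredictionSet, B: int = 1000, seed: int = 0,
                 method: str = "empirical") -> tuple[float, float]:
    """95% bootstrap confidence interval for ``metric`` on ``pred``.

    Rows are resampled with replacement *within each allele* (stratified),
    preserving allele composition.  ``method="empirical"`` gives the basic /
    reverse-percentile pivot interval (2*theta_hat - q_{97.5}, 2*theta_hat -
    q_{2.5}); ``method="percentile"`` the plain percentile interval.
    Deterministic given ``seed``.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    theta = metric(pred)
    if theta is None:
        raise ValueError("metric undefined on the full prediction set")
    rng = np.random.default_rng(seed)
    base = pred.frame.reset_index(drop=True)
    pred = PredictionSet(base)
    groups = [grp.index.to_numpy()
              for _, grp in base.groupby("allele", sort=True)]
    stats = []
    failures = 0
    for _ in range(B):
        take = np.concatenate([g[rng.integers(0, len(g), len(g))]
                               for g in groups])
        rep = PredictionSet(pred.frame.take(take).reset_index(drop=True))
        val = metric(rep)
        if val is None:
            failures += 1
        else:
            stats.append(val)
    if failures > 0.01 * B:
        logger.warning("metric undefined on %d of %d bootstrap replicates; "
                       "dropped", failures, B)
    lo_q, hi_q = np.quantile(stats, [0.025, 0.975])
    if method == "empirical":
        return (2 * theta - hi_q, 2 * theta - lo_q)
    if method == "percentile":
        return (float(lo_q), float(hi_q))
    raise ValueError(f"unknown bootstrap method {method!r}")


def multi_run_report(points: Sequence[float],
                     cis: Sequence[tuple[float, float]]):
    """Mean point estimate over k runs with a conservative error bar.

    The error is the maximum over runs of the larger one-sided CI deviation
    max(theta - lo, hi - theta).  Requires k >= 2 runs of identical structure.
    """
    if len(points) != len(cis):
        raise ValueError("points and CIs differ in length")
    if len(points) < 2:
        raise ValueError("need at least 2 runs")
    devs = [max(p - lo, hi - p) for p, (lo, hi) in zip(points, cis)]
    return float(np.mean(points)), float(max(devs))


# ---------------------------------------------------------------------------
# Train/test similarity audit
# ---------------------------------------------------------------------------

def _peptides_of(items) -> list[str]:
    if len(items) and isinstance(items[0], AffinityRecord):
        return [r.peptide for r in items]
    return list(items)


def similarity_overlap_audit(train, test, threshold: float = 0.8) -> pd.DataFrame:
    """Flag test peptides with a same-length training peptide at or above
    ``threshold`` positional identity (matching positions / length).

    Different-length pairs are never compared.  Returns a DataFrame with
    columns ``peptide``, ``match``, ``identity`` for the flagged test
    peptides (empty when the split is clean).
    """
    train_p = _peptides_of(train)
    test_p = _peptides_of(test)
    if not train_p or not test_p:
        raise ValueError("both sets must be nonempty")

    by_len: dict[int, np.ndarray] = {}
    by_len_seq: dict[int, list[str]] = {}
    for p in train_p:
        by_len_seq.setdefault(len(p), []).append(p)
    for L, seqs in by_len_seq.items():
        by_len[L] = np.frombuffer("".join(seqs).encode(), dtype=np.uint8) \
            .reshape(len(seqs), L)

    flagged = []
    seen = set()
    for p in test_p:
        if p in seen:
            continue
        seen.add(p)
        L = len(p)
        if L not in by_len:
            continue
        arr = np.frombuffer(p.encode(), dtype=np.uint8)
        ident = (by_len[L] == arr).mean(axis=1)
        j = int(ident.argmax())
        if ident[j] >= threshold:
            flagged.append((p, by_len_seq[L][j], float(ident[j])))
    return pd.DataFrame(flagged, columns=["peptide", "match", "identity"])
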