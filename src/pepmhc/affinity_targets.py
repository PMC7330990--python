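"""IC50 <-> regression-target transform, binder labels, and the censored MSE loss.

Affinities are regressed on the log-transformed scale

    y = 1 - log(IC50) / log(cap),    cap = 50000 nM by default,

so y = 1 at IC50 = 1 nM (strong binder) and y = 0 at the cap (non-binder);
y is monotonically *decreasing* in IC50.  Censored measurements ("IC50 < b"
or "IC50 > b") become one-sided constraints in y-space.  Because the
transform is order-reversing, an IC50 upper bound (``<``) becomes a *lower*
bound on y (``AT_LEAST``) and vice versa.

The censored mean-squared-error loss penalizes only violations of the
constraint, which lets qualitative records (e.g. non-binders known only as
"IC50 above the assay limit") contribute to training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .peptide_data import AffinityRecord, Inequality

logger = logging.getLogger(__name__)

#: Default IC50 cap in nM; measurements at or above it map to y = 0.
DEFAULT_CAP_NM: float = 50000.0


class BoundDirection(IntEnum):
    """Constraint type in transformed (y) space."""

    POINT = 0     # exact target: penalize both directions
    AT_LEAST = 1  # y_true is a lower bound: penalize under-prediction only
    AT_MOST = 2   # y_true is an upper bound: penalize over-prediction only


#: IC50-space inequality -> y-space bound (the log transform reverses order).
INEQUALITY_TO_DIRECTION = {
    Inequality.EQ: BoundDirection.POINT,
    Inequality.LT: BoundDirection.AT_LEAST,
    Inequality.GT: BoundDirection.AT_MOST,
}


@dataclass(frozen=True)
class TargetSpec:
    """A regression target in y-space with its censoring direction."""

    y: float
    direction: BoundDirection = BoundDirection.POINT
    cap_nm: float = DEFAULT_CAP_NM


@dataclass(frozen=True)
class BinderThreshold:
    """Binder definition: IC50 strictly below ``threshold_nm``.

    Conventional values: 500 nM for MHC class I, 1000 nM for class II,
    100000 nM for assays censored at a high bound.
    """

    threshold_nm: float = 500.0


def ic50_to_target(ic50_nm, cap_nm: float = DEFAULT_CAP_NM):
    """Map IC50 in nM to y = clip(1 - log(ic50)/log(cap), 0, 1).

    Strictly decreasing on (1, cap); accepts scalars or arrays.
    """
    ic50 = np.asarray(ic50_nm, dtype=float)
    if np.any(ic50 <= 0):
        raise ValueError("ic50_nm must be positive")
    if not cap_nm > 1:
        raise ValueError("cap_nm must exceed 1 nM")
    y = np.clip(1.0 - np.log(ic50) / np.log(cap_nm), 0.0, 1.0)
    return float(y) if np.isscalar(ic50_nm) else y


def target_to_ic50(y, cap_nm: float = DEFAULT_CAP_NM):
    """Inverse transform: ic50 = cap^(1-y).

    Model outputs are unconstrained reals, so values outside [0, 1] are
    clipped (with a logged warning) before inversion.
    """
    arr = np.asarray(y, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        logger.warning("clipping %d target value(s) outside [0, 1] before "
                       "IC50 conversion", int(np.sum((arr < 0) | (arr > 1))))
        arr = np.clip(arr, 0.0, 1.0)
    ic50 = cap_nm ** (1.0 - arr)
    return float(ic50) if np.isscalar(y) else ic50


def record_to_target(rec: AffinityRecord, cap_nm: float = DEFAULT_CAP_NM) -> TargetSpec:
    """Build the y-space target for one record, mapping its censoring side."""
    return TargetSpec(
        y=ic50_to_target(rec.ic50_nm, cap_nm),
        direction=INEQUALITY_TO_DIRECTION[rec.inequality],
        cap_nm=cap_nm,
    )


def censored_residual(y_pred, y_true, direction):
    """Signed residual whose square is the censored loss.

    POINT: y_pred - y_true; AT_LEAST: min(y_pred - y_true, 0) (only
    under-prediction); AT_MOST: max(y_pred - y_true, 0) (only
    over-prediction).  The loss gradient w.r.t. y_pred is 2 * residual.
    """
    y_pred = np.asarray(y_pred, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    direction = np.asarray(direction, dtype=int)
    diff = y_pred - y_true
    r = np.where(
        direction == BoundDirection.POINT,
        diff,
        np.where(
            direction == BoundDirection.AT_LEAST,
            np.minimum(diff, 0.0),
            np.maximum(diff, 0.0),
        ),
    )
    return r


def censored_mse(y_pred, y_true, direction) -> float:
    """Mean censored squared error over a batch (scalars broadcast)."""
    r = censored_residual(y_pred, y_true, direction)
    return float(np.mean(np.square(r)))


def binder_label(ic50_nm, thr: BinderThreshold = BinderThreshold()):
    """1 iff IC50 is strictly below the threshold; vectorized."""
    ic50 = np.asarray(ic50_nm, dtype=float)
    if np.any(ic50 <= 0) or thr.threshold_nm <= 0:
        raise ValueError("IC50 values and threshold must be positive")
    lab = (ic50 < thr.threshold_nm).astype(int)
    return int(lab) if np.isscalar(ic50_nm) else lab
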