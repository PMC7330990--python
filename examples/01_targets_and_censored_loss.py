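"""Affinity records, the log-IC50 regression target, and the censored loss.

Builds a handful of measurements (including a qualitative non-binder known
only as "IC50 > 50000 nM"), maps them to regression targets and shows how
the censored loss treats each kind.
"""

import numpy as np

from pepmhc import AffinityRecord, Inequality, MeasurementKind
from pepmhc.affinity_targets import (
    censored_mse, censored_residual, ic50_to_target, record_to_target,
    target_to_ic50,
)

records = [
    AffinityRecord("HLA-A-0201", "SIINFEKL", 120.0),
    AffinityRecord("HLA-A-0201", "ACDEFGHIK", 45000.0),
    AffinityRecord("HLA-A-0201", "LMNPQRSTV", 50000.0, Inequality.GT,
                   MeasurementKind.qualitative),
]

print("peptide      IC50 (nM)  qualifier  target y   direction")
for rec in records:
    t = record_to_target(rec)
    print(f"{rec.peptide:<12}{rec.ic50_nm:>10.0f}  {rec.inequality.value:^9}"
          f"  {t.y:>8.4f}   {t.direction.name}")

# y = 1 - log(IC50)/log(50000): 1 nM -> y=1 (strong binder), cap -> y=0.
# The 500 nM class I binder threshold sits at y ~ 0.426:
print(f"\n500 nM threshold in y-space: {ic50_to_target(500.0):.4f}")
print(f"y = 0.5 corresponds to {target_to_ic50(0.5):.0f} nM")

# The censored loss penalizes the qualitative non-binder (direction AT_MOST,
# bound y=0) only if the model predicts it as a binder:
y_true = np.array([record_to_target(r).y for r in records])
direction = np.array([int(record_to_target(r).direction) for r in records])
for y_pred in (np.array([0.8, 0.1, -0.1]), np.array([0.8, 0.1, 0.3])):
    print(f"\npredictions {y_pred} -> loss {censored_mse(y_pred, y_true, direction):.4f}"
          f"  (per-record residuals {censored_residual(y_pred, y_true, direction)})")
# The first prediction satisfies the censoring bound (residual 0 for the
# non-binder); the second over-predicts it and is penalized for that row only.
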