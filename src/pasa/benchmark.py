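"""Replay of the published per-sample SVM prediction table.

The package bundles the per-sample test predictions reported for the
39-sample ex vivo skin cohort (12 normal, 15 SCC, 12 BCC): in each of three
cross-validation cycles, 13 held-out samples (4 normal, 5 SCC, 4 BCC;
classes coded 1/2/3) were classified by SVMs trained on a single-wavelength
feature (1210, 1310 or 1700 nm) or on all 21 band features.  Replaying this
table through :func:`pasa.classify.evaluate_predictions` reproduces every
published testing accuracy, the per-feature-set means, and the pooled
per-class diagnostic accuracies.

Two internal quirks of the published table are taken as-is rather than
"repaired".  First, it lists the same 13 test-sample identifiers in all
three cycles, which is inconsistent with rotating three-fold test sets
over 39 samples; the replay makes no attempt to reconstruct the intended
fold rotation.  Second, its cycle-3 / 1210 nm per-sample predictions
contain 10 correct of 13 (76.9%), while the published summary row prints
69.2% (9/13) for that cell and propagates it into the published 1210 nm
mean of 69.2; this module reports what the per-sample predictions actually
give (76.9, and a 1210 nm mean of 71.8), since altering a prediction to
match the summary would fabricate data.  Every other accuracy replays
exactly as published.  Training accuracies are reported in the source
table but the underlying training predictions are not, so they are carried
here only as display constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .classify import evaluate_predictions

__all__ = [
    "CYCLES",
    "FEATURE_SETS",
    "PredictionTable",
    "load_prediction_table",
    "cycle_accuracy",
    "mean_accuracy",
    "pooled_class_accuracy",
    "REPORTED_TRAINING_ACCURACY",
]

CYCLES = (1, 2, 3)
FEATURE_SETS = ("1210", "1310", "1700", "all")
_COLUMNS = ["true_cat", "samp"] + [f"c{c}_{f}" for c in CYCLES for f in FEATURE_SETS]

#: training accuracies as published (not recomputable from the predictions)
REPORTED_TRAINING_ACCURACY = {
    (1, "1210"): 95.8, (1, "1310"): 75.8, (1, "1700"): 95.8, (1, "all"): 100.0,
    (2, "1210"): 92.5, (2, "1310"): 100.0, (2, "1700"): 96.7, (2, "all"): 100.0,
    (3, "1210"): 83.3, (3, "1310"): 96.7, (3, "1700"): 92.5, (3, "all"): 95.8,
}


def _round1(x: float) -> float:
    """Round half-up to one decimal, as the published percentages are."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PredictionTable:
    """Validated per-sample prediction table (one row per test sample)."""

    rows: pd.DataFrame

    @property
    def n_samples(self) -> int:
        return len(self.rows)

    def class_counts(self) -> dict[int, int]:
        return self.rows["true_cat"].value_counts().to_dict()

    def predictions(self, cycle: int, feature_set: str) -> np.ndarray:
        return self.rows[_column(cycle, feature_set)].to_numpy()

    @property
    def true_categories(self) -> np.ndarray:
        return self.rows["true_cat"].to_numpy()


def _column(cycle: int, feature_set: str) -> str:
    if cycle not in CYCLES:
        raise ValueError(f"cycle must be one of {CYCLES}")
    feature_set = str(feature_set).removesuffix(" nm").lower()
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature set must be one of {FEATURE_SETS}")
    return f"c{cycle}_{feature_set}"


def load_prediction_table(path=None) -> PredictionTable:
    """Load and validate a prediction table; default is the bundled cohort table."""
    if path is None:
        ref = resources.files("pasa").joinpath("data/skin_svm_predictions.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    if df.empty:
        raise ValueError("prediction table is empty")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"prediction table lacks columns: {missing}")
    label_cols = ["true_cat"] + [c for c in _COLUMNS if c.startswith("c")]
    for i, row in df.iterrows():
        for col in label_cols:
            v = row[col]
            if not (float(v).is_integer() and int(v) in (1, 2, 3)):
                raise ValueError(
                    f"row {i + 1}: invalid label {v!r} in column {col!r} "
                    "(labels must be 1, 2 or 3)")
    return PredictionTable(rows=df[_COLUMNS].astype(int))


def cycle_accuracy(table: PredictionTable, cycle: int, feature_set: str) -> float:
    """Testing accuracy (%) of one cycle and feature set, to one decimal."""
    pred = table.predictions(cycle, feature_set)
    correct = int(np.sum(pred == table.true_categories))
    return _round1(100.0 * correct / table.n_samples)


def mean_accuracy(table: PredictionTable, feature_set: str) -> float:
    """Mean (%) of the three cycle testing accuracies, to one decimal."""
    return _round1(np.mean([cycle_accuracy(table, c, feature_set) for c in CYCLES]))


def pooled_class_accuracy(table: PredictionTable, feature_set: str
                          ) -> tuple[float, float, float]:
    """Per-class accuracy (%) with predictions pooled across the three cycles."""
    true_pooled, pred_pooled = [], []
    for c in CYCLES:
        true_pooled.extend(table.true_categories)
        pred_pooled.extend(table.predictions(c, feature_set))
    ev = evaluate_predictions(true_pooled, pred_pooled)
    return tuple(_round1(a) for a in ev.per_class_accuracy)
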