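"""Severity sub-task: classify pathogenic variants as benign or severe.

Raw labels come in three states — ``benign``, ``benign/severe`` (reported
both ways in the literature) and ``severe`` — and are merged to a binary
target with severe as the positive class (``benign/severe`` counts as
severe).  Two adjustments distinguish this task from pathogenicity
prediction:

* the initial/final amino-acid one-hot features are excluded (with them the
  models memorize mutation patterns and fail to generalize), enforced here
  as a hard guard on the feature matrix;
* because the classes are imbalanced toward severe, the decision threshold
  is tuned to maximize balanced accuracy **on the training data only** and
  then applied unchanged to the test set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pipeline import EnsembleSpec, FittedEnsemble, compute_metrics
from .variants import DataValidationError

SEVERITY_MERGE = {"benign": 0, "benign/severe": 1, "severe": 1}

ENDPOINT_PREFIXES = ("initial_aa_", "final_aa_")


def merge_severity_labels(raw: pd.DataFrame) -> pd.DataFrame:
    """Binarize three-state severity labels (benign=0; benign/severe and severe=1)."""
    unknown = set(raw["label"]) - set(SEVERITY_MERGE)
    if unknown:
        raise DataValidationError(f"unknown severity labels {sorted(unknown)}")
    out = raw.copy()
    out["raw_label"] = raw["label"]
    out["label"] = [SEVERITY_MERGE[l] for l in raw["label"]]
    return out


def check_no_endpoint_features(feature_matrix: pd.DataFrame) -> None:
    """Reject matrices carrying initial/final residue one-hots (overfitting guard)."""
    leaking = [
        c for c in feature_matrix.columns if c.startswith(ENDPOINT_PREFIXES)
    ]
    if leaking:
        raise DataValidationError(
            "severity models must not see endpoint residue identities; "
            f"drop columns {leaking[:4]}{'...' if len(leaking) > 4 else ''}"
        )


def optimize_threshold(scores, labels) -> tuple[float, float]:
    """Decision threshold maximizing balanced accuracy on training scores.

    Candidate cuts are the midpoints between adjacent sorted unique scores,
    plus 0.5 (so the optimized threshold never does worse than the default).
    Ties are broken toward the candidate closest to 0.5.  Returns
    ``(threshold, balanced_accuracy_at_threshold)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("both classes required to optimize a threshold")
    uniq = np.unique(scores)
    candidates = [0.5]
    candidates += [float((a + b) / 2.0) for a, b in zip(uniq[:-1], uniq[1:])]
    pos, neg = labels == 1, labels == 0
    best_t, best_ba = 0.5, -np.inf
    for t in candidates:
        pred = scores >= t
        sens = (pred & pos).sum() / pos.sum()
        spec = (~pred & neg).sum() / neg.sum()
        ba = (sens + spec) / 2.0
        if ba > best_ba or (ba == best_ba and abs(t - 0.5) < abs(best_t - 0.5)):
            best_t, best_ba = t, ba
    return best_t, float(best_ba)


@dataclass
class ThresholdedModel:
    """A fitted ensemble plus the training-optimized decision threshold."""

    ensemble: FittedEnsemble
    threshold: float
    training_balanced_accuracy: float

    @property
    def spec(self) -> EnsembleSpec:
        return self.ensemble.spec

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.ensemble.predict_proba(X)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(int)

    def evaluate(self, X: pd.DataFrame, y) -> dict:
        return compute_metrics(y, self.predict_proba(X), threshold=self.threshold)
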