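"""RBF max-margin scorer, score normalization and the hybrid average.

The margin scorer is a support vector machine with a radial-basis-function
kernel over the selected fingerprint bits (defaults g = 0.1, c = 6, j = 1;
j is the cost ratio applied to errors on the active class).  Its decision
value and the potency score live on different scales, so each is mapped to
[−1, 1] by an affine min–max transform calibrated on training-set scores
(out-of-range test scores are clipped).  The hybrid score is the arithmetic
mean of the two normalized scores; classification is active iff the score
strictly exceeds the threshold (default 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import joblib
import numpy as np
from sklearn.svm import SVC

from .data import ACTIVE, INACTIVE, LabeledDataset, subset_fingerprints


@dataclass
class ScoreCalibration:
    """Observed raw-score range on the training set, per score type."""

    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        if self.minimum > self.maximum:
            raise ValueError("calibration minimum exceeds maximum")

    @property
    def degenerate(self) -> bool:
        return self.minimum == self.maximum

    @classmethod
    def from_scores(cls, scores) -> "ScoreCalibration":
        s = np.asarray(scores, dtype=float)
        if s.size == 0:
            raise ValueError("cannot calibrate on an empty score list")
        return cls(float(s.min()), float(s.max()))


@dataclass
class HybridScore:
    norm_potency: float
    norm_margin: float
    hybrid: float


@dataclass
class MarginModel:
    """Trained RBF-SVM scorer bound to its fingerprint name order."""

    svc: SVC
    fingerprint_names: list[str]
    g: float
    c: float
    j: float
    seed: int
    calibration: Optional[ScoreCalibration] = None

    def decision_scores(self, X) -> np.ndarray:
        """Real-valued decision values; positive means active."""
        X = np.asarray(X)
        if X.shape[1] != len(self.fingerprint_names):
            raise ValueError(
                f"expected {len(self.fingerprint_names)} fingerprint columns, "
                f"got {X.shape[1]}"
            )
        return self.svc.decision_function(X)

    def score_dataset(self, ds: LabeledDataset) -> np.ndarray:
        missing = [
            n for n in self.fingerprint_names
            if n not in ds.matrix.fingerprint_names
        ]
        if missing:
            raise ValueError(f"table missing training fingerprints: {missing}")
        sub = subset_fingerprints(ds, self.fingerprint_names)
        return self.decision_scores(sub.matrix.values)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "MarginModel":
        model = joblib.load(path)
        if not isinstance(model, MarginModel):
            raise TypeError(f"{path} does not contain a MarginModel")
        return model


def train_margin_scorer(
    ds: LabeledDataset,
    g: float = 0.1,
    c: float = 6.0,
    j: float = 1.0,
    seed: int = 0,
) -> MarginModel:
    """Fit the RBF margin scorer on a labeled fingerprint dataset.

    g is the kernel width (gamma), c the error cost, and j the extra cost
    multiplier for misclassified actives (j = 1 treats both classes alike).
    Deterministic for fixed (dataset, parameters, seed).
    """
    y = ds.y
    if ds.n_active < 2 or ds.n_inactive < 2:
        raise ValueError("need ≥ 2 molecules per class to train")
    svc = SVC(
        kernel="rbf", gamma=g, C=c,
        class_weight={1: j, 0: 1.0},
        random_state=seed,
    )
    svc.fit(ds.matrix.values.astype(float), y)
    model = MarginModel(
        svc=svc, fingerprint_names=list(ds.matrix.fingerprint_names),
        g=g, c=c, j=j, seed=seed,
    )
    model.calibration = ScoreCalibration.from_scores(
        model.decision_scores(ds.matrix.values)
    )
    return model


def normalize_scores(raw, cal: ScoreCalibration) -> np.ndarray:
    """Affine map sending [cal.min, cal.max] → [−1, 1], clipped outside.

    Monotone non-decreasing, so training-set ranks (hence AUC) are
    preserved.  A degenerate calibration (min = max) maps everything to 0.
    """
    s = np.asarray(raw, dtype=float)
    if cal.degenerate:
        return np.zeros_like(s)
    out = 2.0 * (s - cal.minimum) / (cal.maximum - cal.minimum) - 1.0
    return np.clip(out, -1.0, 1.0)


def hybrid_score(norm_potency: float, norm_margin: float) -> HybridScore:
    """Arithmetic mean of the two normalized component scores."""
    for v in (norm_potency, norm_margin):
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"normalized score {v!r} outside [−1, 1]")
    return HybridScore(
        norm_potency=float(norm_potency), norm_margin=float(norm_margin),
        hybrid=(float(norm_potency) + float(norm_margin)) / 2.0,
    )


def classify_hybrid(score: float, threshold: float = 0.0) -> str:
    """Active iff the hybrid score strictly exceeds the threshold."""
    return ACTIVE if score > threshold else INACTIVE
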