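"""Classifier metrics and the repeated stratified cross-validation protocol.

Metrics follow the standard four-count definitions: sensitivity and
specificity as percents, accuracy as a percent of all molecules, the
Matthews correlation coefficient (MCC) with the zero-denominator → 0
convention, the false-positive rate, and a rank-based AUC (tied scores get
averaged ranks, which equals the trapezoidal area under the full ROC sweep).

The evaluation protocol is stratified five-fold cross-validation repeated
(default 20 times).  Everything fit from data — the selected fingerprint
list, the similarity reference set, the margin model, and the score
calibrations — is refit inside each training portion, so held-out scores
never see their own molecule.  Per repeat the five folds' test scores are
pooled; metrics are computed on a fixed threshold grid (−1.0 … 1.0 in steps
of 0.2) and the report is the mean over repeats with standard deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, KFold

THRESHOLD_GRID: tuple[float, ...] = tuple(np.round(np.arange(-1.0, 1.01, 0.2), 10))


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricSet:
    """Sensitivity/specificity/accuracy in percent; mcc, fpr, auc unitless."""

    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    fpr: float
    auc: float = math.nan

    def rounded(self, ndigits: int = 2) -> "MetricSet":
        return MetricSet(
            round(self.sensitivity, ndigits), round(self.specificity, ndigits),
            round(self.accuracy, ndigits), round(self.mcc, ndigits),
            round(self.fpr, ndigits),
            round(self.auc, ndigits) if not math.isnan(self.auc) else math.nan,
        )


def mcc_from_counts(tp: int, fp: int, tn: int, fn: int) -> float:
    """Four-count MCC; any zero factor in the denominator gives 0."""
    num = tp * tn - fp * fn
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0:
        return 0.0
    return num / math.sqrt(den)


def confusion_metrics(cc: ConfusionCounts) -> MetricSet:
    """MetricSet (AUC excluded) from a confusion matrix."""
    if cc.total == 0:
        raise ValueError("empty confusion matrix")
    n_act = cc.tp + cc.fn
    n_ina = cc.tn + cc.fp
    sens = 100.0 * cc.tp / n_act if n_act else 0.0
    spec = 100.0 * cc.tn / n_ina if n_ina else 0.0
    acc = 100.0 * (cc.tp + cc.tn) / cc.total
    fpr = cc.fp / n_ina if n_ina else 0.0
    return MetricSet(sens, spec, acc, mcc_from_counts(cc.tp, cc.fp, cc.tn, cc.fn), fpr)


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, pd.DataFrame]:
    """Rank-statistic AUC (ties averaged) plus ROC points for plotting.

    The rank form is the Mann–Whitney statistic
    U / (n_pos · n_neg), identical to the trapezoidal area under the ROC
    curve traced over every distinct threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required to compute AUC")
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-s, kind="mergesort")
    ys = y[order]
    ss = s[order]
    tps = np.cumsum(ys == 1)
    fps = np.cumsum(ys == 0)
    # one ROC point per distinct threshold, plus the (0,0) origin
    last = np.r_[ss[1:] != ss[:-1], True]
    points = pd.DataFrame({
        "threshold": np.r_[np.inf, ss[last]],
        "fpr": np.r_[0.0, fps[last] / n_neg],
        "tpr": np.r_[0.0, tps[last] / n_pos],
    })
    return float(auc), points


@dataclass
class CVConfig:
    folds: int = 5
    repeats: int = 20
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be ≥ 2")
        if self.repeats < 1:
            raise ValueError("repeats must be ≥ 1")


@dataclass
class CVResult:
    """Averaged cross-validation report for one scoring method."""

    method: str
    thresholds: tuple[float, ...]
    mean: dict[float, MetricSet]          # threshold -> mean metrics
    std: dict[float, MetricSet]           # threshold -> std over repeats
    auc_mean: float
    auc_std: float
    pooled_scores: np.ndarray             # last repeat, molecule order
    pooled_labels: np.ndarray
    selected_per_fold: list[list[str]] = field(default_factory=list)
    fold_assignments: list[np.ndarray] = field(default_factory=list)  # per repeat

    def at(self, threshold: float = 0.0) -> MetricSet:
        key = min(self.mean, key=lambda t: abs(t - threshold))
        return self.mean[key]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.thresholds:
            m = self.mean[t]
            rows.append({
                "threshold": t, "sensitivity": m.sensitivity,
                "specificity": m.specificity, "accuracy": m.accuracy,
                "mcc": m.mcc, "fpr": m.fpr, "auc": self.auc_mean,
            })
        return pd.DataFrame(rows)


def _metrics_at(scores: np.ndarray, y: np.ndarray, threshold: float) -> MetricSet:
    pred = scores > threshold  # boundary equality → inactive
    tp = int(np.count_nonzero(pred & (y == 1)))
    fp = int(np.count_nonzero(pred & (y == 0)))
    fn = int(np.count_nonzero(~pred & (y == 1)))
    tn = int(np.count_nonzero(~pred & (y == 0)))
    return confusion_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))


def cross_validate(
    ds,
    method: str,
    cfg: CVConfig = CVConfig(),
    selection_cutoff: float = 0.2,
    top_k: Optional[int] = None,
    min_k: int = 10,
    fixed_fingerprints: Optional[Sequence[str]] = None,
    svm_params: Optional[dict] = None,
    thresholds: Sequence[float] = THRESHOLD_GRID,
) -> CVResult:
    """Repeated stratified k-fold evaluation of one scoring method.

    method: "potency" (raw potency score), "margin" (normalized SVM decision
    value) or "hybrid" (mean of normalized potency and margin scores).
    Feature selection is refit inside each training fold unless
    ``fixed_fingerprints`` pins a global list; after the strict MCC cutoff
    the top ``min_k`` ranked fingerprints are kept as a floor so scoring
    remains defined on signal-free data.
    """
    from . import features
    from .data import subset_fingerprints

    if method not in ("potency", "margin", "hybrid"):
        raise ValueError(f"unknown method {method!r}")
    y = ds.y
    n = len(y)
    counts = np.bincount(y, minlength=2)
    if cfg.stratified and counts.min() < cfg.folds:
        raise ValueError(
            f"need ≥ {cfg.folds} molecules per class for stratified "
            f"{cfg.folds}-fold CV, have {counts.min()}"
        )

    thresholds = tuple(float(t) for t in thresholds)
    ss = np.random.SeedSequence(cfg.seed)
    repeat_seeds = [int(s) % (2**31) for s in ss.generate_state(cfg.repeats)]

    per_repeat: dict[float, list[MetricSet]] = {t: [] for t in thresholds}
    aucs: list[float] = []
    selected_per_fold: list[list[str]] = []
    fold_assignments: list[np.ndarray] = []
    X = ds.matrix.values

    for rseed in repeat_seeds:
        splitter = (
            StratifiedKFold(cfg.folds, shuffle=True, random_state=rseed)
            if cfg.stratified
            else KFold(cfg.folds, shuffle=True, random_state=rseed)
        )
        pooled_scores = np.full(n, np.nan)
        assignment = np.full(n, -1, dtype=int)
        for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
            assignment[test_idx] = fold
            train = _take(ds, train_idx)
            test = _take(ds, test_idx)

            if fixed_fingerprints is not None:
                names = list(fixed_fingerprints)
            else:
                stats = features.all_fingerprint_stats(train)
                names = features.select_fingerprints(
                    stats, mcc_cutoff=selection_cutoff, top_k=top_k
                )
                if len(names) < min_k:
                    names = features.ranked_fingerprints(stats)[:min_k]
            selected_per_fold.append(names)
            train_s = subset_fingerprints(train, names)
            test_s = subset_fingerprints(test, names)

            scores = _score_fold(train_s, test_s, method, svm_params, rseed)
            pooled_scores[test_idx] = scores

        assert not np.isnan(pooled_scores).any()  # every molecule tested once
        fold_assignments.append(assignment)
        for t in thresholds:
            per_repeat[t].append(_metrics_at(pooled_scores, y, t))
        auc, _ = roc_auc(pooled_scores, y)
        aucs.append(auc)

    mean = {}
    std = {}
    for t in thresholds:
        ms = per_repeat[t]
        cols = np.array([
            [m.sensitivity, m.specificity, m.accuracy, m.mcc, m.fpr] for m in ms
        ])
        mean[t] = MetricSet(*cols.mean(axis=0))
        std[t] = MetricSet(*cols.std(axis=0))
    return CVResult(
        method=method, thresholds=thresholds, mean=mean, std=std,
        auc_mean=float(np.mean(aucs)), auc_std=float(np.std(aucs)),
        pooled_scores=pooled_scores, pooled_labels=y,
        selected_per_fold=selected_per_fold,
        fold_assignments=fold_assignments,
    )


def _take(ds, idx: np.ndarray):
    from .data import FingerprintMatrix, LabeledDataset

    mat = ds.matrix
    return LabeledDataset(
        FingerprintMatrix(
            [mat.molecule_ids[i] for i in idx],
            list(mat.fingerprint_names),
            mat.values[idx],
        ),
        [ds.labels[i] for i in idx],
    )


def _score_fold(train, test, method: str, svm_params: Optional[dict], seed: int):
    """Fit on the training portion only; return real-valued test scores on
    the method's decision scale (potency raw, margin/hybrid normalized)."""
    from . import hybrid as hy
    from .potency import score_queries

    need_potency = method in ("potency", "hybrid")
    need_margin = method in ("margin", "hybrid")

    if need_potency:
        pot_test = score_queries(test.matrix.values, train)
        if method == "potency":
            return pot_test
        pot_train = score_queries(
            train.matrix.values, train, exclude_self=True
        )
        pot_cal = hy.ScoreCalibration.from_scores(pot_train)
    if need_margin:
        params = svm_params or {}
        model = hy.train_margin_scorer(train, seed=seed, **params)
        mar_test = model.decision_scores(test.matrix.values)
        mar_cal = hy.ScoreCalibration.from_scores(
            model.decision_scores(train.matrix.values)
        )
        if method == "margin":
            return hy.normalize_scores(mar_test, mar_cal)
    return np.array([
        hy.hybrid_score(p, m).hybrid
        for p, m in zip(
            hy.normalize_scores(pot_test, pot_cal),
            hy.normalize_scores(mar_test, mar_cal),
        )
    ])


def sweep_report(results: Sequence[tuple[str, MetricSet]]) -> pd.DataFrame:
    """Tabulate (row label, MetricSet) pairs — a threshold sweep or a
    fingerprint-count sweep — as a delimited-text-ready frame."""
    cols = ["sensitivity", "specificity", "accuracy", "mcc", "fpr", "auc"]
    rows = []
    for label, m in results:
        r = m.rounded()
        rows.append({"configuration": label, **{c: getattr(r, c) for c in cols}})
    return pd.DataFrame(rows, columns=["configuration", *cols])
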