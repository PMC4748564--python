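"""Single-fingerprint discrimination statistics and MCC-based selection.

Each binary fingerprint is scored on its standalone ability to separate
active from inactive molecules.  The per-class bit means F^A and F^I give a
per-molecule compound score

    C_score = F^A - F^I   if the bit is set,
              F^I - F^A   otherwise,

and the molecule is called active when C_score exceeds a threshold.  Because
one bit yields at most two distinct scores, the full threshold sweep reduces
to midpoints between the distinct observed scores plus sentinels beyond the
extremes.  The threshold maximizing the Matthews correlation coefficient
(MCC) defines the fingerprint's standalone performance; fingerprints with
MCC above a cutoff (default 0.2) are kept for model building.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data import LabeledDataset
from .evaluate import ConfusionCounts, confusion_metrics, roc_auc


@dataclass
class FeatureStats:
    """Standalone classification performance of one fingerprint bit."""

    fingerprint_name: str
    mean_active: float       # F^A: fraction of actives with the bit set
    mean_inactive: float     # F^I: fraction of inactives with the bit set
    best_threshold: float    # on the C_score scale
    orientation: int         # bit value that predicts active (1 or 0)
    sensitivity: float       # percent
    specificity: float       # percent
    accuracy: float          # percent
    mcc: float
    fpr: float
    auc: float
    degenerate: bool = False  # constant column: no discriminating power


def class_bit_means(ds: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-fingerprint (F^A, F^I): mean bit value within each class.

    Exact rational semantics: sum of bits over class size, computed in
    integer arithmetic before the single division.
    """
    y = ds.y
    na, ni = ds.n_active, ds.n_inactive
    if na == 0 or ni == 0:
        raise ValueError("both classes must be non-empty to compute bit means")
    X = ds.matrix.values
    ones_active = (X[y == 1].sum(axis=0)).astype(np.int64)
    ones_inactive = (X[y == 0].sum(axis=0)).astype(np.int64)
    return ones_active / na, ones_inactive / ni


def compound_score(bit: int, mean_active: float, mean_inactive: float) -> float:
    """C_score of one molecule for one fingerprint."""
    if bit not in (0, 1):
        raise ValueError(f"bit must be 0 or 1, got {bit!r}")
    d = mean_active - mean_inactive
    return d if bit == 1 else -d


def _best_threshold(
    scores: np.ndarray, y: np.ndarray
) -> tuple[float, ConfusionCounts]:
    """Sweep 'active iff score > t' over midpoints of distinct scores plus
    sentinels; maximize MCC, ties broken toward higher sensitivity, then
    lower threshold."""
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([distinct[0] - 1.0], mids, [distinct[-1] + 1.0]))
    best: Optional[tuple[float, float, float, ConfusionCounts]] = None
    n_act = int((y == 1).sum())
    n_ina = int((y == 0).sum())
    for t in thresholds:
        pred = scores > t
        tp = int(np.count_nonzero(pred & (y == 1)))
        fp = int(np.count_nonzero(pred & (y == 0)))
        cc = ConfusionCounts(tp=tp, fp=fp, fn=n_act - tp, tn=n_ina - fp)
        m = confusion_metrics(cc)
        key = (m.mcc, m.sensitivity, -t)
        if best is None or key > (best[0], best[1], -best[2]):
            best = (m.mcc, m.sensitivity, float(t), cc)
    assert best is not None
    return best[2], best[3]


def single_fingerprint_performance(ds: LabeledDataset, name: str) -> FeatureStats:
    """Best-threshold C_score performance of one fingerprint column."""
    if name not in ds.matrix.fingerprint_names:
        raise KeyError(f"unknown fingerprint {name!r}")
    col = ds.matrix.values[:, ds.matrix.fingerprint_names.index(name)]
    y = ds.y
    fa, fi = class_bit_means(ds)
    i = ds.matrix.fingerprint_names.index(name)
    fa_i, fi_i = float(fa[i]), float(fi[i])
    d = fa_i - fi_i
    scores = np.where(col == 1, d, -d).astype(float)
    # constant column, or equal bit frequency in both classes: every
    # threshold gives chance-level separation (MCC 0, AUC 1/2)
    degenerate = bool(col.min() == col.max() or d == 0.0)

    t, cc = _best_threshold(scores, y)
    m = confusion_metrics(cc)
    auc, _ = roc_auc(scores, y)
    return FeatureStats(
        fingerprint_name=name, mean_active=fa_i, mean_inactive=fi_i,
        best_threshold=t, orientation=1 if d >= 0 else 0,
        sensitivity=m.sensitivity, specificity=m.specificity,
        accuracy=m.accuracy, mcc=m.mcc, fpr=m.fpr, auc=auc,
        degenerate=degenerate,
    )


def all_fingerprint_stats(ds: LabeledDataset) -> list[FeatureStats]:
    """FeatureStats for every fingerprint column, in matrix order."""
    return [
        single_fingerprint_performance(ds, name)
        for name in ds.matrix.fingerprint_names
    ]


def select_fingerprints(
    stats: Sequence[FeatureStats],
    mcc_cutoff: float = 0.2,
    top_k: Optional[int] = None,
) -> list[str]:
    """Rank by MCC (desc; ties: accuracy desc, name asc) and keep names with
    MCC strictly above the cutoff; top_k truncates after filtering."""
    if not stats:
        raise ValueError("no fingerprint statistics to select from")
    ranked = sorted(stats, key=lambda s: (-s.mcc, -s.accuracy, s.fingerprint_name))
    names = [s.fingerprint_name for s in ranked if s.mcc > mcc_cutoff]
    if top_k is not None:
        names = names[:top_k]
    return names


def ranked_fingerprints(stats: Sequence[FeatureStats]) -> list[str]:
    """All fingerprint names in selection rank order (no cutoff)."""
    ranked = sorted(stats, key=lambda s: (-s.mcc, -s.accuracy, s.fingerprint_name))
    return [s.fingerprint_name for s in ranked]
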