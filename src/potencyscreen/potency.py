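"""Dual Tanimoto similarity and the potency score.

Two Tanimoto coefficients are computed between binary fingerprint vectors:
Ts1 over the set bits (the usual |x∧y| / |x∨y|) and Ts0 over the unset bits
(the same coefficient on the complemented vectors).  For a query molecule,
the highest Ts1 and Ts0 against the active references (HaTs1, HaTs0) and
against the inactive references (HnTs1, HnTs0) give the potency score

    Ps = max(HaTs1, HaTs0) − max(HnTs1, HnTs0),

a value in [−1, 1] that is positive when the query resembles its nearest
active reference more than its nearest inactive one.  Classification is by
thresholding Ps (active iff Ps > threshold; equality → inactive).

An all-zero pair (or all-one pair, for Ts0) makes the Tanimoto denominator
zero; absence of shared evidence is not similarity, so the score is 0 and a
degeneracy flag is set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data import ACTIVE, INACTIVE, LabeledDataset


@dataclass
class SimilarityPair:
    """Ts1/Ts0 between two molecules, with zero-denominator flags."""

    ts1: float
    ts0: float
    degenerate_ts1: bool = False
    degenerate_ts0: bool = False


@dataclass
class PotencyResult:
    """Nearest-reference similarities and potency score for one query."""

    ha_ts1: float
    ha_ts0: float
    hn_ts1: float
    hn_ts0: float
    nearest_active_id: str
    nearest_inactive_id: str
    potency: float


def _as_bits(v) -> np.ndarray:
    a = np.asarray(v)
    if a.ndim != 1:
        raise ValueError("bit vector must be one-dimensional")
    if a.size == 0:
        raise ValueError("bit vector must have length ≥ 1")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("bit vector entries must be 0 or 1")
    return a.astype(bool)


def tanimoto_present(x, y) -> float:
    """Ts1 = |x∧y| / |x∨y|; 0 if both vectors are all-zero."""
    bx, by = _as_bits(x), _as_bits(y)
    if bx.size != by.size:
        raise ValueError(f"length mismatch: {bx.size} vs {by.size}")
    union = int(np.count_nonzero(bx | by))
    if union == 0:
        return 0.0
    return int(np.count_nonzero(bx & by)) / union


def tanimoto_absent(x, y) -> float:
    """Ts0: Tanimoto over unset bits = Ts1 on the complemented vectors."""
    bx, by = _as_bits(x), _as_bits(y)
    if bx.size != by.size:
        raise ValueError(f"length mismatch: {bx.size} vs {by.size}")
    return tanimoto_present(~bx, ~by)


def similarity_pair(x, y) -> SimilarityPair:
    """Both coefficients at once, with degeneracy flags."""
    bx, by = _as_bits(x), _as_bits(y)
    if bx.size != by.size:
        raise ValueError(f"length mismatch: {bx.size} vs {by.size}")
    deg1 = not (bx.any() or by.any())
    deg0 = bool(bx.all() and by.all())
    return SimilarityPair(
        ts1=tanimoto_present(bx, by), ts0=tanimoto_absent(bx, by),
        degenerate_ts1=deg1, degenerate_ts0=deg0,
    )


def _bulk_ts1(Q: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Ts1 between every query row and every reference row.

    Queries × references matrix; zero-union pairs score 0.
    """
    # float64 keeps the small integer counts exact, so the bulk path agrees
    # bit-for-bit with the scalar tanimoto_present
    Qf = Q.astype(np.float64)
    Rf = R.astype(np.float64)
    inter = Qf @ Rf.T
    union = Qf.sum(axis=1)[:, None] + Rf.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim


def bulk_similarities(
    Q: np.ndarray, R: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(Ts1, Ts0) matrices between query rows and reference rows."""
    Q = np.asarray(Q, dtype=np.uint8)
    R = np.asarray(R, dtype=np.uint8)
    return _bulk_ts1(Q, R), _bulk_ts1(1 - Q, 1 - R)


def potency(ha_ts1: float, ha_ts0: float, hn_ts1: float, hn_ts0: float) -> float:
    """Ps = max(HaTs1, HaTs0) − max(HnTs1, HnTs0)."""
    for v in (ha_ts1, ha_ts0, hn_ts1, hn_ts0):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"similarity {v!r} outside [0, 1]")
    return max(ha_ts1, ha_ts0) - max(hn_ts1, hn_ts0)


def nearest_similarities(
    query, refs: LabeledDataset, exclude_id: Optional[str] = None
) -> PotencyResult:
    """Highest Ts1/Ts0 of a query against active and inactive references.

    exclude_id removes one reference molecule before the maxima are taken
    (guards identical-duplicate leakage when scoring a reference against its
    own set).  The nearest id per class comes from whichever of Ts1/Ts0 is
    larger at its maximum (tie → the Ts1 neighbor).
    """
    q = _as_bits(query).astype(np.uint8)[None, :]
    mat = refs.matrix
    if q.shape[1] != len(mat.fingerprint_names):
        raise ValueError(
            f"query has {q.shape[1]} bits, references have "
            f"{len(mat.fingerprint_names)}"
        )
    keep = np.ones(len(mat.molecule_ids), dtype=bool)
    if exclude_id is not None and exclude_id in mat.molecule_ids:
        keep[mat.molecule_ids.index(exclude_id)] = False
    y = refs.y
    act = np.flatnonzero(keep & (y == 1))
    ina = np.flatnonzero(keep & (y == 0))
    if act.size == 0 or ina.size == 0:
        raise ValueError("need ≥ 1 active and ≥ 1 inactive reference")

    ts1, ts0 = bulk_similarities(q, mat.values[np.r_[act, ina]])
    ts1, ts0 = ts1[0], ts0[0]
    na = act.size
    ha1_i, ha0_i = int(ts1[:na].argmax()), int(ts0[:na].argmax())
    hn1_i, hn0_i = int(ts1[na:].argmax()), int(ts0[na:].argmax())
    ha_ts1, ha_ts0 = float(ts1[ha1_i]), float(ts0[ha0_i])
    hn_ts1, hn_ts0 = float(ts1[na + hn1_i]), float(ts0[na + hn0_i])

    ids = mat.molecule_ids
    nearest_active = ids[act[ha1_i if ha_ts1 >= ha_ts0 else ha0_i]]
    nearest_inactive = ids[ina[hn1_i if hn_ts1 >= hn_ts0 else hn0_i]]
    return PotencyResult(
        ha_ts1=ha_ts1, ha_ts0=ha_ts0, hn_ts1=hn_ts1, hn_ts0=hn_ts0,
        nearest_active_id=nearest_active, nearest_inactive_id=nearest_inactive,
        potency=potency(ha_ts1, ha_ts0, hn_ts1, hn_ts0),
    )


def score_queries(
    Q: np.ndarray, refs: LabeledDataset, exclude_self: bool = False
) -> np.ndarray:
    """Potency score for a block of query rows against a reference set.

    With exclude_self=True, Q must be the reference matrix itself (row
    aligned) and each molecule's own row is masked before the maxima —
    used when calibrating on the training set.
    """
    Q = np.asarray(Q, dtype=np.uint8)
    y = refs.y
    R = refs.matrix.values
    if exclude_self and Q.shape != R.shape:
        raise ValueError("exclude_self requires Q to be the reference matrix")
    ts1, ts0 = bulk_similarities(Q, R)
    if exclude_self:
        np.fill_diagonal(ts1, -np.inf)
        np.fill_diagonal(ts0, -np.inf)
    act = y == 1
    ina = y == 0
    if not act.any() or not ina.any():
        raise ValueError("need ≥ 1 active and ≥ 1 inactive reference")
    if exclude_self and (act.sum() < 2 or ina.sum() < 2):
        raise ValueError("exclude_self needs ≥ 2 references per class")
    ha = np.maximum(ts1[:, act].max(axis=1), ts0[:, act].max(axis=1))
    hn = np.maximum(ts1[:, ina].max(axis=1), ts0[:, ina].max(axis=1))
    return ha - hn


def classify_potency(ps: float, threshold: float = 0.0) -> str:
    """Active iff the potency score strictly exceeds the threshold."""
    return ACTIVE if ps > threshold else INACTIVE
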