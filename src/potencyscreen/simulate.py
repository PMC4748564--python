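"""Synthetic labeled fingerprint datasets with known planted structure.

The generator emulates the statistical shape of a screening benchmark:

* informative bits whose presence probability differs between actives
  (``p_active``) and inactives (``p_inactive``) — the signal that MCC-based
  selection should recover;
* background bits with a common presence probability in both classes;
* optionally, a fraction of actives that are noisy clones of other actives
  (each bit flipped independently with rate ``epsilon``), mimicking the
  chemical-series redundancy that nearest-neighbor similarity methods
  exploit;
* optionally, XOR-structured bit pairs whose single-bit class frequencies
  are equal (invisible to per-bit selection) but whose interaction carries
  the label — signal only a non-linear margin model can use.

Everything is a deterministic function of the seed; the informative bit
names are returned as ground truth for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import ACTIVE, INACTIVE, FingerprintMatrix, LabeledDataset


@dataclass
class SimConfig:
    n_active: int = 1000
    n_inactive: int = 1000
    n_fingerprints: int = 100
    n_informative: int = 10
    p_active: float = 0.9        # informative-bit presence rate in actives
    p_inactive: float = 0.1      # ... in inactives
    p_background: float = 0.3    # uninformative-bit presence rate, both classes
    duplicate_fraction: float = 0.3  # actives replaced by noisy clones
    epsilon: float = 0.05        # per-bit flip rate in cloned actives
    n_xor_pairs: int = 0         # label-carrying bit pairs with null marginals
    p_xor: float = 0.9           # P(pair matches its class pattern)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_active, self.p_inactive, self.p_background,
                  self.duplicate_fraction, self.epsilon, self.p_xor):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p!r} outside [0, 1]")
        if self.n_informative + 2 * self.n_xor_pairs > self.n_fingerprints:
            raise ValueError(
                "informative + XOR bits exceed total fingerprint count"
            )
        if self.n_active < 1 or self.n_inactive < 1:
            raise ValueError("need at least one molecule per class")


def generate_dataset(cfg: SimConfig) -> tuple[LabeledDataset, list[str]]:
    """Draw a labeled dataset; returns (dataset, informative bit names).

    Informative bits are named ``FP<i>_info``, XOR bits ``FP<i>_xor``,
    background bits ``FP<i>``.  Class sizes match the config exactly; the
    row order is shuffled by the seed.  The returned ground-truth list
    contains the informative and XOR bit names.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_active + cfg.n_inactive
    k_info = cfg.n_informative
    k_xor = 2 * cfg.n_xor_pairs
    k_bg = cfg.n_fingerprints - k_info - k_xor

    names = (
        [f"FP{i + 1}_info" for i in range(k_info)]
        + [f"FP{k_info + i + 1}_xor" for i in range(k_xor)]
        + [f"FP{k_info + k_xor + i + 1}" for i in range(k_bg)]
    )

    def draw_class(n_rows: int, p_info: float, active: bool) -> np.ndarray:
        blocks = []
        if k_info:
            blocks.append(rng.random((n_rows, k_info)) < p_info)
        for _ in range(cfg.n_xor_pairs):
            b = rng.random(n_rows) < 0.5
            follows = rng.random(n_rows) < cfg.p_xor
            # actives: bits differ; inactives: bits agree (noisy)
            second = (~b if active else b) ^ ~follows
            blocks.append(np.column_stack([b, second]))
        if k_bg:
            blocks.append(rng.random((n_rows, k_bg)) < cfg.p_background)
        return np.hstack(blocks).astype(np.uint8)

    X_act = draw_class(cfg.n_active, cfg.p_active, active=True)
    X_ina = draw_class(cfg.n_inactive, cfg.p_inactive, active=False)

    n_clone = int(round(cfg.duplicate_fraction * cfg.n_active))
    if n_clone and cfg.n_active - n_clone >= 1:
        templates = rng.integers(0, cfg.n_active - n_clone, size=n_clone)
        clones = X_act[templates].copy()
        flips = rng.random(clones.shape) < cfg.epsilon
        clones[flips] ^= 1
        X_act[cfg.n_active - n_clone:] = clones

    X = np.vstack([X_act, X_ina])
    labels = np.array([ACTIVE] * cfg.n_active + [INACTIVE] * cfg.n_inactive)
    order = rng.permutation(n)
    ids = [f"S{i + 1}" for i in range(n)]
    ds = LabeledDataset(
        FingerprintMatrix(ids, names, X[order]), list(labels[order])
    )
    return ds, names[: k_info + k_xor]


def analytic_single_bit_mcc(
    p_active: float, p_inactive: float,
    n_active: int = 1, n_inactive: int = 1,
) -> float:
    """Expected MCC of "predict active iff bit set" from expected counts.

    TP = p_active·NA, FN = (1−p_active)·NA, FP = p_inactive·NI,
    TN = (1−p_inactive)·NI; the four-count MCC of these expectations is the
    large-sample limit of the observed single-bit MCC.
    """
    for p in (p_active, p_inactive):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p!r} outside [0, 1]")
    tp = p_active * n_active
    fn = (1.0 - p_active) * n_active
    fp = p_inactive * n_inactive
    tn = (1.0 - p_inactive) * n_inactive
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(den)
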