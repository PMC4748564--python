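"""Functional-group frequency and mean-count profiling.

For each group G and each class, two statistics are reported: F_G, the
percent of class molecules containing the group at least once, and M_G, the
mean number of occurrences per molecule.  Occurrences are distinct
substructure matches with symmetric duplicates merged (e.g. glycerol has
three ROH matches, not six).

Group definitions live in an editable tab-separated file of
"name<TAB>SMARTS" lines; a default vocabulary (ROH, ROR, RCOR, RCOOR, RCHO,
RCOOH, RNH2, R2NH, R3N, RCN, RNO2, RSH, RSR, RX, phenol, aromatic N) ships
with the package.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .data import ACTIVE, INACTIVE, DataError, MoleculeSet


@dataclass
class GroupDefinition:
    name: str
    smarts: str

    def pattern(self) -> "Chem.Mol":
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise DataError(
                f"invalid substructure pattern for group {self.name!r}: "
                f"{self.smarts!r}"
            )
        return patt


@dataclass
class GroupCountTable:
    """Occurrence counts per molecule × group, with class labels."""

    molecule_ids: list[str]
    group_names: list[str]
    counts: np.ndarray  # int64, (n_molecules, n_groups)
    labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise DataError("group counts must be non-negative")
        if self.counts.shape != (len(self.molecule_ids), len(self.group_names)):
            raise DataError("count matrix shape inconsistent with id/name lists")
        if len(self.labels) != len(self.molecule_ids):
            raise DataError("one label required per molecule")

    def class_rows(self, label: str) -> np.ndarray:
        rows = np.fromiter(
            (l == label for l in self.labels), dtype=bool, count=len(self.labels)
        )
        if not rows.any():
            raise DataError(f"no molecules with label {label!r}")
        return rows


def read_group_definitions(path: Optional[str | Path] = None) -> list[GroupDefinition]:
    """Read "name<TAB>pattern" lines ('#' comments); default: shipped file."""
    if path is None:
        text = (
            importlib.resources.files("potencyscreen")
            .joinpath("resources/functional_groups.tsv")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    defs: list[GroupDefinition] = []
    seen: set[str] = set()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, smarts = line.split("\t")
        if name in seen:
            raise DataError(f"duplicate group name {name!r}")
        seen.add(name)
        d = GroupDefinition(name, smarts)
        d.pattern()  # validate eagerly so bad files fail fast
        defs.append(d)
    return defs


def match_groups(
    mols: MoleculeSet,
    defs: Sequence[GroupDefinition],
    labels: Optional[Sequence[str]] = None,
) -> GroupCountTable:
    """Count distinct (symmetry-deduplicated) matches of each group."""
    patterns = [(d.name, d.pattern()) for d in defs]
    ids: list[str] = []
    rows: list[list[int]] = []
    for mid, mol in mols.mols():
        ids.append(mid)
        rows.append([
            len(mol.GetSubstructMatches(p, uniquify=True)) for _, p in patterns
        ])
    lab = list(labels) if labels is not None else [ACTIVE] * len(ids)
    return GroupCountTable(
        molecule_ids=ids,
        group_names=[n for n, _ in patterns],
        counts=np.asarray(rows, dtype=np.int64).reshape(len(ids), len(patterns)),
        labels=lab,
    )


def group_frequency(gct: GroupCountTable, label: str) -> pd.Series:
    """F_G: percent of class molecules containing each group (count ≥ 1)."""
    rows = gct.class_rows(label)
    present = (gct.counts[rows] >= 1).mean(axis=0)
    return pd.Series(100.0 * present, index=gct.group_names, name=f"F_G[{label}]")


def group_mean_count(gct: GroupCountTable, label: str) -> pd.Series:
    """M_G: mean occurrence count of each group within the class."""
    rows = gct.class_rows(label)
    return pd.Series(
        gct.counts[rows].mean(axis=0), index=gct.group_names,
        name=f"M_G[{label}]",
    )


def group_profile(gct: GroupCountTable) -> pd.DataFrame:
    """Tidy per-group, per-class profile with both F_G and M_G columns."""
    records = []
    for label in (ACTIVE, INACTIVE):
        if not any(l == label for l in gct.labels):
            continue
        fg = group_frequency(gct, label)
        mg = group_mean_count(gct, label)
        for name in gct.group_names:
            records.append({
                "group": name, "class": label,
                "frequency_percent": fg[name], "mean_count": mg[name],
            })
    return pd.DataFrame(records)
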