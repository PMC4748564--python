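"""Molecule sets, binary fingerprint matrices and labeled datasets.

A fingerprint matrix holds one row per molecule and one named binary column
per fingerprint bit (presence/absence of a substructure or property).  A
labeled dataset attaches an active/inactive class label to each row — the
substrate for feature selection, similarity scoring and model training.

Fingerprint provenance is treated as data: any named 0/1 columns read from a
table are accepted (e.g. an external generator's output), while native
computation provides RDKit MACCS keys and a shipped SMARTS substructure key
set.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys

RDLogger.DisableLog("rdApp.*")

ACTIVE = "active"
INACTIVE = "inactive"

# label vocabulary accepted in tables, case-insensitive
_LABEL_MAP = {
    "1": ACTIVE, "active": ACTIVE, "anticancer": ACTIVE,
    "0": INACTIVE, "inactive": INACTIVE, "non-anticancer": INACTIVE,
}


class DataError(ValueError):
    """Malformed molecule or fingerprint input."""


@dataclass
class MoleculeSet:
    """Ordered (molecule_id, SMILES) records; unparseable SMILES are flagged."""

    records: list[tuple[str, str]]
    invalid_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [mid for mid, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({m for m in ids if ids.count(m) > 1})
            raise DataError(f"duplicate molecule ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [mid for mid, _ in self.records]

    def mols(self, skip_invalid: bool = False):
        """Yield (id, rdkit Mol) pairs in record order."""
        for mid, smi in self.records:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                if skip_invalid:
                    continue
                raise DataError(f"unparseable SMILES for molecule {mid!r}: {smi!r}")
            yield mid, mol


@dataclass
class FingerprintMatrix:
    """Molecules × named binary fingerprints (values strictly 0/1)."""

    molecule_ids: list[str]
    fingerprint_names: list[str]
    values: np.ndarray  # uint8, shape (n_molecules, n_fingerprints)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.molecule_ids),
            len(self.fingerprint_names),
        ):
            raise DataError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.molecule_ids)} ids × {len(self.fingerprint_names)} names"
            )
        if len(set(self.molecule_ids)) != len(self.molecule_ids):
            raise DataError("duplicate molecule ids in fingerprint matrix")
        if len(set(self.fingerprint_names)) != len(self.fingerprint_names):
            raise DataError("duplicate fingerprint names")
        bad = (self.values > 1).nonzero()
        if bad[0].size:
            r, c = bad[0][0], bad[1][0]
            raise DataError(
                f"non-binary value at row {self.molecule_ids[r]!r}, "
                f"column {self.fingerprint_names[c]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, molecule_id: str) -> np.ndarray:
        return self.values[self.molecule_ids.index(molecule_id)]


@dataclass
class LabeledDataset:
    """Fingerprint matrix plus per-molecule active/inactive label."""

    matrix: FingerprintMatrix
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.matrix.molecule_ids):
            raise DataError("one label required per molecule")
        bad = sorted({l for l in self.labels if l not in (ACTIVE, INACTIVE)})
        if bad:
            raise DataError(f"unknown class labels: {bad}")

    @property
    def y(self) -> np.ndarray:
        """Binary label vector, 1 = active."""
        return np.fromiter(
            (1 if l == ACTIVE else 0 for l in self.labels), dtype=np.int8,
            count=len(self.labels),
        )

    @property
    def n_active(self) -> int:
        return int(self.y.sum())

    @property
    def n_inactive(self) -> int:
        return len(self.labels) - self.n_active


def normalize_label(token: str) -> str:
    """Map a raw label token to 'active'/'inactive' (case-insensitive)."""
    key = str(token).strip().lower()
    if key not in _LABEL_MAP:
        raise DataError(f"unmappable class label {token!r}")
    return _LABEL_MAP[key]


def read_smiles(path: str | Path) -> MoleculeSet:
    """Read a .smi-style file: one "SMILES[ id]" per non-empty line.

    Missing ids are auto-assigned "M<line number>" (1-based).  Unparseable
    SMILES are kept and flagged in ``invalid_ids`` rather than dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[tuple[str, str]] = []
    explicit: set[str] = set()
    invalid: set[str] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split(None, 1)
        smi = parts[0]
        if len(parts) == 2:
            mid = parts[1].strip()
            if mid in explicit:
                raise DataError(f"duplicate molecule id {mid!r} at line {lineno}")
            explicit.add(mid)
        else:
            mid = f"M{lineno}"
        if Chem.MolFromSmiles(smi) is None:
            invalid.add(mid)
        records.append((mid, smi))
    return MoleculeSet(records, invalid_ids=invalid)


def _substructure_keys() -> list[tuple[str, "Chem.Mol"]]:
    src = (
        importlib.resources.files("potencyscreen")
        .joinpath("resources/substructure_keys.tsv")
        .read_text()
    )
    keys = []
    for line in src.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, smarts = line.split("\t")
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:  # shipped file is validated by tests
            raise DataError(f"invalid SMARTS for substructure key {name!r}")
        keys.append((name, patt))
    return keys


def compute_fingerprints(
    mols: MoleculeSet, scheme: str, on_invalid: str = "error"
) -> FingerprintMatrix:
    """Compute a named binary fingerprint matrix for a molecule set.

    Schemes: ``"maccs"`` — the 166 MACCS structural keys (columns
    ``maccs1..maccs166``); ``"substructure"`` — the shipped SMARTS key set
    (columns ``sub<name>``).  Deterministic for fixed input and backend.

    on_invalid: "error" aborts on an unparseable molecule, "skip" drops it.
    """
    if scheme not in ("maccs", "substructure"):
        raise DataError(f"unknown fingerprint scheme {scheme!r}")
    if on_invalid not in ("error", "skip"):
        raise DataError(f"on_invalid must be 'error' or 'skip', got {on_invalid!r}")

    ids: list[str] = []
    rows: list[np.ndarray] = []
    if scheme == "maccs":
        names = [f"maccs{i}" for i in range(1, 167)]
        for mid, mol in mols.mols(skip_invalid=(on_invalid == "skip")):
            bv = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
            arr = np.zeros(167, dtype=np.uint8)
            arr[list(bv.GetOnBits())] = 1
            ids.append(mid)
            rows.append(arr[1:])
    else:
        patterns = _substructure_keys()
        names = [f"sub_{name}" for name, _ in patterns]
        for mid, mol in mols.mols(skip_invalid=(on_invalid == "skip")):
            arr = np.fromiter(
                (mol.HasSubstructMatch(p) for _, p in patterns),
                dtype=np.uint8, count=len(patterns),
            )
            ids.append(mid)
            rows.append(arr)
    values = np.vstack(rows) if rows else np.zeros((0, len(names)), dtype=np.uint8)
    return FingerprintMatrix(ids, names, values)


def read_fingerprint_table(path: str | Path) -> LabeledDataset:
    """Read a CSV fingerprint table: molecule_id, label, then 0/1 columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0] != "molecule_id":
        raise DataError("first column must be 'molecule_id'")
    if "label" not in df.columns:
        raise DataError("missing 'label' column")
    ids = df["molecule_id"].tolist()
    if len(set(ids)) != len(ids):
        raise DataError("duplicate molecule ids in table")
    labels = [normalize_label(t) for t in df["label"]]
    fp_cols = [c for c in df.columns if c not in ("molecule_id", "label")]
    values = df[fp_cols].to_numpy()
    ok = np.isin(values, (0, 1))
    if not ok.all():
        r, c = np.argwhere(~ok)[0]
        raise DataError(
            f"non-binary cell {values[r, c]!r} at row {ids[r]!r}, "
            f"column {fp_cols[c]!r}"
        )
    return LabeledDataset(FingerprintMatrix(ids, fp_cols, values), labels)


def write_fingerprint_table(ds: LabeledDataset, path: str | Path) -> None:
    """Write a dataset as CSV; round-trips bit-exactly with the reader."""
    df = pd.DataFrame(ds.matrix.values, columns=ds.matrix.fingerprint_names)
    df.insert(0, "label", ds.labels)
    df.insert(0, "molecule_id", ds.matrix.molecule_ids)
    df.to_csv(path, index=False)


def subset_fingerprints(ds: LabeledDataset, names: Sequence[str]) -> LabeledDataset:
    """Select/reorder fingerprint columns; rows and labels are untouched."""
    index = {n: i for i, n in enumerate(ds.matrix.fingerprint_names)}
    unknown = [n for n in names if n not in index]
    if unknown:
        raise DataError(f"unknown fingerprint names: {unknown}")
    cols = [index[n] for n in names]
    mat = FingerprintMatrix(
        list(ds.matrix.molecule_ids), list(names), ds.matrix.values[:, cols]
    )
    return LabeledDataset(mat, list(ds.labels))
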