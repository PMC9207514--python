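"""Molecular featurization: SMILES -> numeric feature tables.

Three descriptor families are computed with RDKit:

* ``ecfp6``  — Morgan circular fingerprint, radius 3, folded to 2048 bits.
* ``maccs``  — the 166 MACCS structural keys. RDKit emits 167 bits with
  index 0 as an unused padding bit; that bit is dropped so each vector has
  exactly 166 entries.
* ``rdkit2d`` — RDKit's full panel of 2D physico-chemical descriptors
  (counts, charges, topological indices...); non-finite values are imputed
  to 0 with a warning. The exact column count depends on the RDKit version.

Any externally computed table (e.g. a 1,613-column macrocycle descriptor
set) is consumed through :func:`load_feature_csv`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator

from .decoy_selection import Fingerprint, FingerprintSet
from .errors import FeaturizationError, InputError

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")  # rdkit parse chatter; failures surface as errors

__all__ = [
    "CompoundRecord",
    "FeatureMatrix",
    "DESCRIPTORS",
    "read_smiles_file",
    "featurize",
    "ecfp6_fingerprints",
    "load_feature_csv",
    "save_feature_csv",
    "scale_min_max",
]

DESCRIPTORS = ("ecfp6", "maccs", "rdkit2d")

ECFP6_BITS = 2048
ECFP6_RADIUS = 3
MACCS_KEYS = 166


@dataclass
class CompoundRecord:
    id: str
    smiles: str
    label: int | None = None  # 1 related, 0 unrelated, None unknown


@dataclass
class FeatureMatrix:
    ids: list[str]
    descriptor_name: str
    matrix: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise InputError("feature matrix shape does not match id count")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.matrix.shape[1])]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def read_smiles_file(path: str | Path, label: int | None = None) -> list[CompoundRecord]:
    """Read a .smi file: one molecule per line, `SMILES[<ws>id]`."""
    path = Path(path)
    records: list[CompoundRecord] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smiles = parts[0]
        cid = parts[1] if len(parts) > 1 else f"{path.stem}_{lineno}"
        records.append(CompoundRecord(id=cid, smiles=smiles, label=label))
    if not records:
        raise InputError(f"no compounds found in {path}")
    return records


def _parse_all(records: list[CompoundRecord]) -> list[Chem.Mol]:
    mols = []
    bad = []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            bad.append((rec.id, rec.smiles))
        mols.append(mol)
    if bad:
        listing = "; ".join(f"{cid}: {smi!r}" for cid, smi in bad)
        raise FeaturizationError(f"unparseable SMILES for {len(bad)} record(s): {listing}")
    return mols


def featurize(records: list[CompoundRecord], descriptor: str) -> FeatureMatrix:
    """Compute one descriptor family for every record; all-or-nothing."""
    if descriptor not in DESCRIPTORS:
        raise InputError(
            f"unknown descriptor {descriptor!r}; choose one of {DESCRIPTORS} "
            "or load a precomputed table with load_feature_csv"
        )
    if not records:
        raise InputError("no compound records to featurize")
    mols = _parse_all(records)
    ids = [r.id for r in records]

    if descriptor == "ecfp6":
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=ECFP6_RADIUS, fpSize=ECFP6_BITS
        )
        mat = np.zeros((len(mols), ECFP6_BITS))
        for i, mol in enumerate(mols):
            fp = gen.GetFingerprint(mol)
            mat[i, list(fp.GetOnBits())] = 1.0
        names = [f"ecfp6_{i}" for i in range(ECFP6_BITS)]
        return FeatureMatrix(ids, "ecfp6", mat, names)

    if descriptor == "maccs":
        mat = np.zeros((len(mols), MACCS_KEYS))
        for i, mol in enumerate(mols):
            fp = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 is padding
            on = [b - 1 for b in fp.GetOnBits() if b >= 1]
            mat[i, on] = 1.0
        names = [f"maccs_{i + 1}" for i in range(MACCS_KEYS)]
        return FeatureMatrix(ids, "maccs", mat, names)

    # rdkit2d: full 2D descriptor panel
    names = [name for name, _ in Descriptors.descList]
    mat = np.empty((len(mols), len(names)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, mol in enumerate(mols):
            values = Descriptors.CalcMolDescriptors(mol)
            mat[i] = [values[name] for name in names]
    bad = ~np.isfinite(mat)
    if bad.any():
        logger.warning(
            "imputed %d non-finite descriptor value(s) to 0", int(bad.sum())
        )
        mat[bad] = 0.0
    return FeatureMatrix(ids, "rdkit2d", mat, names)


def ecfp6_fingerprints(records: list[CompoundRecord]) -> FingerprintSet:
    """ECFP6 bit-sets for Tanimoto-based decoy selection."""
    mols = _parse_all(records)
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=ECFP6_RADIUS, fpSize=ECFP6_BITS
    )
    fps = [
        Fingerprint(bits=frozenset(int(b) for b in gen.GetFingerprint(m).GetOnBits()),
                    n_bits=ECFP6_BITS)
        for m in mols
    ]
    return FingerprintSet(ids=[r.id for r in records], fingerprints=fps)


def load_feature_csv(
    path: str | Path,
    label_column: str | None = None,
    id_column: str = "id",
) -> tuple[FeatureMatrix, np.ndarray | None]:
    """Load a precomputed feature table (id column + numeric feature columns)."""
    path = Path(path)
    df = pd.read_csv(path)
    if id_column not in df.columns:
        raise InputError(f"{path}: missing id column {id_column!r}")
    ids = df[id_column].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise InputError(f"{path}: duplicate compound ids")
    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise InputError(f"{path}: missing label column {label_column!r}")
        labels = df[label_column].to_numpy()
    drop = [id_column] + ([label_column] if label_column else [])
    feats = df.drop(columns=drop)
    try:
        mat = feats.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        for col in feats.columns:
            coerced = pd.to_numeric(feats[col], errors="coerce")
            if coerced.isna().any() and not feats[col].isna().any():
                row = int(coerced.isna().idxmax())
                raise InputError(
                    f"{path}: non-numeric value in column {col!r}, row {row}"
                ) from exc
        raise InputError(f"{path}: non-numeric feature values") from exc
    fm = FeatureMatrix(ids, path.stem, mat, list(feats.columns))
    return fm, labels


def save_feature_csv(
    fm: FeatureMatrix,
    path: str | Path,
    labels: np.ndarray | None = None,
    label_column: str = "label",
) -> None:
    df = pd.DataFrame(fm.matrix, columns=fm.feature_names)
    df.insert(0, "id", fm.ids)
    if labels is not None:
        df.insert(1, label_column, labels)
    df.to_csv(path, index=False)


def scale_min_max(
    train: FeatureMatrix, apply_to: FeatureMatrix | None = None
) -> tuple[FeatureMatrix, FeatureMatrix | None, dict]:
    """Min-max scale to [0,1] with the training table's column ranges.

    Constant training columns map to 0; out-of-range values in ``apply_to``
    are clipped into [0, 1]. Returns the scaling parameters for reuse.
    """
    if len(train.ids) == 0:
        raise InputError("cannot fit scaling on an empty table")
    col_min = train.matrix.min(axis=0)
    col_max = train.matrix.max(axis=0)
    span = col_max - col_min
    safe = np.where(span > 0, span, 1.0)

    def transform(fm: FeatureMatrix) -> FeatureMatrix:
        out = (fm.matrix - col_min) / safe
        out = np.where(span > 0, out, 0.0)
        out = np.clip(out, 0.0, 1.0)
        return FeatureMatrix(fm.ids, fm.descriptor_name, out, fm.feature_names)

    params = {"col_min": col_min, "col_max": col_max}
    return transform(train), (transform(apply_to) if apply_to else None), params
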