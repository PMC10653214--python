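"""Molecular featurization: 2048-bit ECFP4 fingerprints and affinity co-descriptors.

The fingerprint is the extended-connectivity fingerprint of diameter 4
(radius 2) folded to a fixed length of 2048 bits.  A binding-affinity
co-descriptor can be appended as one extra, scaled column; by default the
scale is chosen so the affinity column's sample standard deviation matches
that of a typical fingerprint bit (0.5), preventing a raw kcal/mol column
from dominating Euclidean distances over 2048 binary bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chemio import MoleculeRecord, mol_from_record
from .errors import DimensionError, FeaturizationError, ParameterError

__all__ = [
    "Descriptor",
    "ecfp4",
    "fingerprint_matrix",
    "tanimoto",
    "augment_with_affinity",
    "augment_matrix",
    "export_dense_csv",
    "export_sparse_coo",
]

DEFAULT_N_BITS = 2048
_TARGET_BIT_STD = 0.5


@dataclass
class Descriptor:
    """Fixed-length numeric vector for one molecule.

    ``values[:n_bits]`` is the binary fingerprint; when ``has_affinity`` the
    vector has one extra trailing entry holding the scaled affinity.
    """

    values: np.ndarray
    n_bits: int
    has_affinity: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = self.n_bits + (1 if self.has_affinity else 0)
        if self.values.shape != (expected,):
            raise DimensionError(
                f"descriptor length {self.values.shape} != expected ({expected},)"
            )

    @property
    def fingerprint(self) -> np.ndarray:
        return self.values[: self.n_bits]


_GENERATORS: dict[int, object] = {}


def _generator(n_bits: int):
    gen = _GENERATORS.get(n_bits)
    if gen is None:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
        _GENERATORS[n_bits] = gen
    return gen


def ecfp4(record: MoleculeRecord | str, n_bits: int = DEFAULT_N_BITS) -> Descriptor:
    """ECFP4 (Morgan radius-2) fingerprint folded to ``n_bits`` bits.

    Deterministic for a given canonical SMILES.  Accepts a record or a bare
    SMILES string; raises :class:`FeaturizationError` naming the molecule on
    failure.
    """
    if n_bits < 1:
        raise ParameterError(f"n_bits must be positive, got {n_bits}")
    if isinstance(record, str):
        mol = Chem.MolFromSmiles(record)
        name = record
    else:
        name = record.id
        try:
            mol = mol_from_record(record)
        except Exception:
            mol = None
    if mol is None:
        raise FeaturizationError(f"cannot featurize molecule {name!r}")
    fp = _generator(n_bits).GetFingerprint(mol)
    values = np.zeros(n_bits, dtype=np.float64)
    values[list(fp.GetOnBits())] = 1.0
    return Descriptor(values=values, n_bits=n_bits)


def fingerprint_matrix(
    records: Sequence[MoleculeRecord], n_bits: int = DEFAULT_N_BITS
) -> np.ndarray:
    """Stack ECFP4 fingerprints into an (n_records, n_bits) float matrix."""
    X = np.zeros((len(records), n_bits), dtype=np.float64)
    for i, rec in enumerate(records):
        X[i] = ecfp4(rec, n_bits=n_bits).values
    return X


def tanimoto(a: Descriptor, b: Descriptor) -> float:
    """Tanimoto similarity of the fingerprint portions.

    Defined as |a AND b| / |a OR b|; two all-zero fingerprints score 1.0.
    """
    if a.n_bits != b.n_bits:
        raise DimensionError(f"fingerprint lengths differ: {a.n_bits} vs {b.n_bits}")
    fa = a.fingerprint.astype(bool)
    fb = b.fingerprint.astype(bool)
    union = int(np.logical_or(fa, fb).sum())
    if union == 0:
        return 1.0
    inter = int(np.logical_and(fa, fb).sum())
    return inter / union


def augment_with_affinity(
    d: Descriptor, affinity: float, scale: float = 1.0
) -> Descriptor:
    """Append ``affinity / scale`` as one extra descriptor entry.

    The fingerprint bits are preserved exactly.
    """
    if d.has_affinity:
        raise ParameterError("descriptor already carries an affinity component")
    if not math.isfinite(affinity):
        raise ValueError(f"affinity must be finite, got {affinity}")
    if not math.isfinite(scale) or scale == 0:
        raise ParameterError(f"scale must be finite and non-zero, got {scale}")
    values = np.concatenate([d.values, [affinity / scale]])
    return Descriptor(values=values, n_bits=d.n_bits, has_affinity=True)


def augment_matrix(
    X: np.ndarray, affinities: np.ndarray, scale: float | None = None
) -> tuple[np.ndarray, float]:
    """Append a scaled affinity column to a fingerprint matrix.

    When ``scale`` is None it is chosen so the scaled column's sample
    standard deviation is 0.5, comparable to a fingerprint bit; a constant
    affinity column falls back to scale 1.0.  Returns (matrix, scale used).
    """
    affinities = np.asarray(affinities, dtype=np.float64)
    if affinities.shape != (X.shape[0],):
        raise DimensionError(
            f"affinity vector length {affinities.shape} != rows {X.shape[0]}"
        )
    if not np.all(np.isfinite(affinities)):
        raise ValueError("affinities must be finite")
    if scale is None:
        sd = float(np.std(affinities, ddof=1)) if len(affinities) > 1 else 0.0
        scale = sd / _TARGET_BIT_STD if sd > 0 else 1.0
    return np.hstack([X, (affinities / scale)[:, None]]), float(scale)


def export_dense_csv(X: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, X, delimiter=",", fmt="%.10g")
    return path


def export_sparse_coo(X: np.ndarray, path: str | Path) -> Path:
    """Write non-zero entries as ``row,col,value`` lines (header included)."""
    path = Path(path)
    rows, cols = np.nonzero(X)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# shape {X.shape[0]} {X.shape[1]}\n")
        fh.write("row,col,value\n")
        for r, c in zip(rows, cols):
            fh.write(f"{r},{c},{X[r, c]:.10g}\n")
    return path
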