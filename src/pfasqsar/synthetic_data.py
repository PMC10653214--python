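"""Seedable synthetic molecule / bioassay / affinity datasets.

Molecules are assembled from a small scaffold grammar (alkyl and aryl cores,
neutral decorations, an optional planted activity motif, an optional
fluorinated tail) so that every emitted SMILES is valid and the ground truth
of each statistical property is known exactly:

* ``p_motif`` of the molecules carry the planted motif (an ester by default);
* activity is Bernoulli with P(active | motif) and P(active | no motif);
* exactly the constructed fraction carries a C-F bond, and a sub-fraction a
  perfluoroalkyl chain of >= 3 carbons;
* a fraction ``labeled_fraction`` of activity labels is observed, the rest
  are masked to UNLABELED.

The ground truth is kept in a sidecar table for assertions and is never fed
to the pipeline under test.  Realism is explicitly not the goal; valid
chemistry and controllable structure are.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .affinity import AffinityTable, write_affinity_table
from .chemio import ActivityLabel, MoleculeRecord, write_molecule_table
from .errors import DataError, ParameterError

__all__ = [
    "FluorinationSpec",
    "AffinityModel",
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_dataset",
    "generate_affinities",
    "write_dataset",
]

DEFAULT_MOTIF_SMARTS = "[CX3](=O)[OX2][#6]"

# Grammar fragments.  Each entry is (smiles_fragment, ends_in_heteroatom).
# Fragments are concatenated left to right; a fragment bonds its first atom
# to the last atom of the string so far.  A "C" bridge is inserted whenever
# the next fragment must not bond directly to a heteroatom (prevents O-O /
# O-CF2 junctions that would break the planted ground truth).
_ARYL_CORES = [("c1ccccc1", False), ("Cc1ccccc1", False), ("c1ccc(C)cc1", False)]
_DECORATIONS = [
    ("", False),
    ("C", False),
    ("CC", False),
    ("O", True),
    ("N", True),
    ("CO", True),
]
_MOTIF_FRAGMENTS = ["C(=O)OC", "OC(=O)C", "C(=O)OCC"]  # all end in carbon
_C3F6_TAIL = "C(F)(F)C(F)(F)C(F)(F)F"
_CF_TAIL = "C(F)(F)F"


@dataclass
class FluorinationSpec:
    """p_cf: P(molecule has any C-F bond); p_c3f6: P(perfluoroalkyl >= C3)."""

    p_cf: float = 0.3
    p_c3f6: float = 0.1


@dataclass
class AffinityModel:
    """Normal affinity model, kcal/mol; actives draw from mu_active."""

    mu_active: float = -6.5
    mu_inactive: float = -4.0
    sd: float = 1.0


@dataclass
class SyntheticSpec:
    n_molecules: int = 2000
    motif_smarts: str = DEFAULT_MOTIF_SMARTS
    p_motif: float = 0.2
    p_active_given_motif: float = 0.9
    p_active_given_no_motif: float = 0.05
    labeled_fraction: float = 0.3
    fluorination: FluorinationSpec = field(default_factory=FluorinationSpec)
    affinity_model: AffinityModel | None = None
    target: str = "T1"
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "p_motif": self.p_motif,
            "p_active_given_motif": self.p_active_given_motif,
            "p_active_given_no_motif": self.p_active_given_no_motif,
            "labeled_fraction": self.labeled_fraction,
            "p_cf": self.fluorination.p_cf,
            "p_c3f6": self.fluorination.p_c3f6,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {p}")
        if self.p_active_given_motif <= self.p_active_given_no_motif:
            raise ParameterError(
                "p_active_given_motif must exceed p_active_given_no_motif "
                "for a recoverable signal"
            )
        if self.fluorination.p_c3f6 > self.fluorination.p_cf:
            raise ParameterError("p_c3f6 cannot exceed p_cf")
        if self.n_molecules < 1:
            raise ParameterError("n_molecules must be positive")
        if self.affinity_model is not None and self.affinity_model.sd <= 0:
            raise ParameterError("affinity sd must be positive")
        if Chem.MolFromSmarts(self.motif_smarts) is None:
            raise ParameterError(f"motif_smarts does not parse: {self.motif_smarts!r}")


@dataclass
class SyntheticDataset:
    records: list[MoleculeRecord]
    truth: pd.DataFrame  # id, smiles, has_motif, has_cf, has_c3f6, true_active, labeled
    spec: SyntheticSpec


def _alkyl_core(rng: np.random.Generator) -> str:
    length = int(rng.integers(2, 9))
    core = "C" * length
    if length >= 3 and rng.random() < 0.3:
        pos = int(rng.integers(1, length - 1))
        core = core[:pos] + "C(C)" + core[pos + 1 :]
    return core


def _assemble(rng: np.random.Generator, with_motif: bool, tail: str | None) -> str:
    if rng.random() < 0.25:
        core, ends_hetero = _ARYL_CORES[int(rng.integers(0, len(_ARYL_CORES)))]
    else:
        core, ends_hetero = _alkyl_core(rng), False
    dec, dec_hetero = _DECORATIONS[int(rng.integers(0, len(_DECORATIONS)))]
    smiles = core + dec
    ends_hetero = dec_hetero if dec else ends_hetero
    if with_motif:
        frag = _MOTIF_FRAGMENTS[int(rng.integers(0, len(_MOTIF_FRAGMENTS)))]
        if ends_hetero:
            smiles += "C"
        smiles += frag
        ends_hetero = False
    if tail is not None:
        if ends_hetero:
            smiles += "C"
        smiles += tail
    return smiles


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate ``spec.n_molecules`` records plus a ground-truth sidecar.

    Fully determined by ``spec.seed``.  Raises :class:`DataError` if the
    grammar ever emits a molecule inconsistent with its planted ground truth
    (which would invalidate every downstream count).
    """
    rng = np.random.default_rng(spec.seed)
    motif_pattern = Chem.MolFromSmarts(spec.motif_smarts)
    from .chemio import _C3F6_PATTERN, _CF_PATTERN  # compiled once at import

    records: list[MoleculeRecord] = []
    rows: list[dict] = []
    width = len(str(spec.n_molecules))
    for i in range(spec.n_molecules):
        has_motif = bool(rng.random() < spec.p_motif)
        u = rng.random()
        if u < spec.fluorination.p_c3f6:
            tail, has_c3f6, has_cf = _C3F6_TAIL, True, True
        elif u < spec.fluorination.p_cf:
            tail, has_c3f6, has_cf = _CF_TAIL, False, True
        else:
            tail, has_c3f6, has_cf = None, False, False
        smiles = _assemble(rng, has_motif, tail)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise DataError(f"grammar emitted unparseable SMILES {smiles!r}")
        if mol.HasSubstructMatch(motif_pattern) != has_motif:
            raise DataError(f"motif ground truth violated for {smiles!r}")
        if mol.HasSubstructMatch(_CF_PATTERN) != has_cf:
            raise DataError(f"C-F ground truth violated for {smiles!r}")
        if mol.HasSubstructMatch(_C3F6_PATTERN) != has_c3f6:
            raise DataError(f"C3F6 ground truth violated for {smiles!r}")

        p_active = (
            spec.p_active_given_motif if has_motif else spec.p_active_given_no_motif
        )
        true_active = bool(rng.random() < p_active)
        labeled = bool(rng.random() < spec.labeled_fraction)
        if labeled:
            label = ActivityLabel.ACTIVE if true_active else ActivityLabel.INACTIVE
        else:
            label = ActivityLabel.UNLABELED

        mol_id = f"M{i + 1:0{width}d}"
        canonical = Chem.MolToSmiles(mol)
        records.append(
            MoleculeRecord(id=mol_id, smiles=canonical, labels={spec.target: label})
        )
        rows.append(
            {
                "id": mol_id,
                "smiles": canonical,
                "has_motif": has_motif,
                "has_cf": has_cf,
                "has_c3f6": has_c3f6,
                "true_active": true_active,
                "labeled": labeled,
            }
        )
    return SyntheticDataset(records=records, truth=pd.DataFrame(rows), spec=spec)


def generate_affinities(
    dataset: SyntheticDataset, model: AffinityModel | None = None
) -> AffinityTable:
    """Draw per-molecule affinities from the ground-truth activity model.

    ACTIVE ground truth draws Normal(mu_active, sd); everything else draws
    Normal(mu_inactive, sd).  Seeded independently of molecule generation so
    the same dataset can receive several affinity realizations.
    """
    model = model or dataset.spec.affinity_model
    if model is None:
        raise ParameterError("no affinity model configured")
    if model.sd <= 0:
        raise ParameterError(f"affinity sd must be positive, got {model.sd}")
    rng = np.random.default_rng([dataset.spec.seed, 1])
    table = AffinityTable()
    truth_active = dict(zip(dataset.truth["id"], dataset.truth["true_active"]))
    for rec in dataset.records:
        mu = model.mu_active if truth_active[rec.id] else model.mu_inactive
        table.entries[(rec.id, dataset.spec.target)] = float(
            rng.normal(mu, model.sd)
        )
    return table


def write_dataset(
    dataset: SyntheticDataset,
    outdir: str | Path,
    affinities: AffinityTable | None = None,
) -> dict[str, Path]:
    """Write molecules.csv (+ ground_truth.csv sidecar, + affinities.csv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "molecules": write_molecule_table(
            dataset.records, outdir / "molecules.csv", targets=[dataset.spec.target]
        )
    }
    truth_path = outdir / "ground_truth.csv"
    dataset.truth.to_csv(truth_path, index=False)
    paths["ground_truth"] = truth_path
    if affinities is not None:
        paths["affinities"] = write_affinity_table(
            affinities, outdir / "affinities.csv"
        )
    return paths
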