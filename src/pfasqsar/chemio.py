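"""Molecule table I/O, SMILES canonicalization, and PFAS membership filters.

Molecule tables are delimited text (CSV/TSV, UTF-8, header row) with an id
column, a SMILES column, and one activity column per biological target.
Activity strings are parsed case-insensitively: {active, 1, true} map to
ACTIVE, {inactive, 0, false} to INACTIVE, and {"", na, n/a, nan, unlabeled,
none} to UNLABELED.

Two structural filters define PFAS dataset membership:

* :func:`filter_cf` keeps molecules with at least one carbon–fluorine bond
  (SMARTS ``[#6][F]``; aromatic C–F counts).
* :func:`filter_c3f6` keeps molecules containing a chain of three or more
  contiguous saturated carbons whose substituents, beyond at most two carbon
  neighbours along the skeleton, are all fluorine.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from rdkit import Chem
from rdkit import RDLogger

from .errors import SchemaError, ValidationError

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ActivityLabel",
    "MoleculeRecord",
    "RejectedRow",
    "ReadResult",
    "TableSchema",
    "parse_label",
    "canonical_smiles",
    "mol_from_record",
    "read_molecule_table",
    "write_molecule_table",
    "read_sdf",
    "write_reject_log",
    "filter_cf",
    "filter_c3f6",
    "CF_SMARTS",
    "C3F6_SMARTS",
]


class ActivityLabel(Enum):
    """Per-target bioassay outcome; UNLABELED is the semi-supervised default."""

    ACTIVE = "active"
    INACTIVE = "inactive"
    UNLABELED = "unlabeled"


_ACTIVE_STRINGS = {"active", "1", "true"}
_INACTIVE_STRINGS = {"inactive", "0", "false"}
_UNLABELED_STRINGS = {"", "na", "n/a", "nan", "unlabeled", "none"}


def parse_label(value: object) -> ActivityLabel:
    """Parse an activity cell into an :class:`ActivityLabel`.

    Raises :class:`ValidationError` for unrecognized strings.
    """
    if value is None:
        return ActivityLabel.UNLABELED
    if isinstance(value, ActivityLabel):
        return value
    text = str(value).strip().lower()
    if text in _ACTIVE_STRINGS:
        return ActivityLabel.ACTIVE
    if text in _INACTIVE_STRINGS:
        return ActivityLabel.INACTIVE
    if text in _UNLABELED_STRINGS:
        return ActivityLabel.UNLABELED
    raise ValidationError(f"unrecognized activity label: {value!r}")


@dataclass
class MoleculeRecord:
    """One molecule: id, canonical SMILES, per-target labels, optional affinities."""

    id: str
    smiles: str
    labels: dict[str, ActivityLabel] = field(default_factory=dict)
    affinity: dict[str, float] = field(default_factory=dict)

    def label_for(self, target: str) -> ActivityLabel:
        return self.labels.get(target, ActivityLabel.UNLABELED)


@dataclass
class RejectedRow:
    """A row excluded on ingest, with enough context to locate it."""

    row: int  # 1-based data-row number (header not counted)
    id: str
    smiles: str
    reason: str


@dataclass
class TableSchema:
    """Column mapping for a molecule table.

    ``activity_cols`` maps target name -> column name; when ``None``, every
    column other than id/smiles is treated as an activity column named after
    itself.
    """

    id_col: str = "id"
    smiles_col: str = "smiles"
    activity_cols: Mapping[str, str] | None = None


@dataclass
class ReadResult:
    """Outcome of :func:`read_molecule_table`."""

    records: list[MoleculeRecord]
    rejects: list[RejectedRow]
    duplicate_smiles: list[tuple[str, str]]  # (kept id, duplicate id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def canonical_smiles(smiles: str) -> str | None:
    """Canonical SMILES, or None if the input does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def mol_from_record(record: MoleculeRecord) -> Chem.Mol:
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise ValidationError(f"record {record.id!r} holds unparseable SMILES")
    return mol


def _infer_delimiter(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_molecule_table(
    path: str | Path,
    schema: TableSchema | None = None,
    sep: str | None = None,
) -> ReadResult:
    """Read a delimited molecule table.

    Rows whose SMILES fail to parse are excluded and collected in
    ``rejects``; row order of valid records is preserved.  Duplicate ids
    raise :class:`ValidationError`; duplicate canonical SMILES are reported
    in ``duplicate_smiles`` but not removed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"molecule table not found: {path}")
    schema = schema or TableSchema()
    delimiter = _infer_delimiter(path, sep)

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header row")
        header = list(reader.fieldnames)
        for col in (schema.id_col, schema.smiles_col):
            if col not in header:
                raise SchemaError(f"{path}: missing mandatory column {col!r}")
        if schema.activity_cols is None:
            activity_cols = {
                c: c for c in header if c not in (schema.id_col, schema.smiles_col)
            }
        else:
            activity_cols = dict(schema.activity_cols)
            for target, col in activity_cols.items():
                if col not in header:
                    raise SchemaError(
                        f"{path}: activity column {col!r} (target {target!r}) missing"
                    )
        if not activity_cols:
            raise SchemaError(f"{path}: at least one activity column is required")

        records: list[MoleculeRecord] = []
        rejects: list[RejectedRow] = []
        duplicates: list[tuple[str, str]] = []
        seen_ids: set[str] = set()
        first_id_by_smiles: dict[str, str] = {}

        for row_num, row in enumerate(reader, start=1):
            mol_id = (row.get(schema.id_col) or "").strip()
            raw_smiles = (row.get(schema.smiles_col) or "").strip()
            if mol_id in seen_ids:
                raise ValidationError(f"duplicate molecule id {mol_id!r}")
            seen_ids.add(mol_id)
            canonical = canonical_smiles(raw_smiles)
            if canonical is None:
                rejects.append(
                    RejectedRow(row_num, mol_id, raw_smiles, "unparseable SMILES")
                )
                continue
            if canonical in first_id_by_smiles:
                duplicates.append((first_id_by_smiles[canonical], mol_id))
            else:
                first_id_by_smiles[canonical] = mol_id
            labels = {
                target: parse_label(row.get(col)) for target, col in activity_cols.items()
            }
            records.append(MoleculeRecord(id=mol_id, smiles=canonical, labels=labels))

    return ReadResult(records=records, rejects=rejects, duplicate_smiles=duplicates)


def write_molecule_table(
    records: Sequence[MoleculeRecord],
    path: str | Path,
    targets: Sequence[str] | None = None,
) -> Path:
    """Write records as CSV readable back by :func:`read_molecule_table`."""
    path = Path(path)
    if targets is None:
        seen: dict[str, None] = {}
        for rec in records:
            for t in rec.labels:
                seen.setdefault(t)
        targets = list(seen)
    if not targets:
        raise ValidationError("cannot write a molecule table with no activity column")
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", *targets])
        for rec in records:
            writer.writerow(
                [rec.id, rec.smiles]
                + [rec.label_for(t).value if rec.label_for(t) is not ActivityLabel.UNLABELED else "" for t in targets]
            )
    return path


def read_sdf(
    path: str | Path,
    id_prop: str | None = None,
    activity_props: Sequence[str] = (),
) -> ReadResult:
    """Read records from an SD file; activity labels come from named SD tags.

    Molecules RDKit cannot parse are rejected.  When ``id_prop`` is None the
    molecule title (first line of each block) is used as the id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SD file not found: {path}")
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    records: list[MoleculeRecord] = []
    rejects: list[RejectedRow] = []
    seen_ids: set[str] = set()
    for idx, mol in enumerate(supplier, start=1):
        if mol is None:
            rejects.append(RejectedRow(idx, "", "", "unparseable SD record"))
            continue
        if id_prop is not None and mol.HasProp(id_prop):
            mol_id = mol.GetProp(id_prop)
        else:
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf-{idx}"
        if mol_id in seen_ids:
            raise ValidationError(f"duplicate molecule id {mol_id!r}")
        seen_ids.add(mol_id)
        labels = {
            prop: parse_label(mol.GetProp(prop) if mol.HasProp(prop) else None)
            for prop in activity_props
        }
        records.append(
            MoleculeRecord(id=mol_id, smiles=Chem.MolToSmiles(mol), labels=labels)
        )
    return ReadResult(records=records, rejects=rejects, duplicate_smiles=[])


def write_reject_log(rejects: Iterable[RejectedRow], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rej in rejects:
            fh.write(f"row {rej.row}\tid={rej.id}\tsmiles={rej.smiles}\t{rej.reason}\n")
    return path


# --- PFAS membership filters -------------------------------------------------

CF_SMARTS = "[#6][F]"

# A "perfluorinated" chain carbon: saturated, no hydrogens, neighbours only
# carbon or fluorine, and at most two carbon neighbours (the chain skeleton).
_PFC = "[CX4H0;!$([CX4][!#6;!F]);!$([CX4]([#6])([#6])[#6])]"
C3F6_SMARTS = f"{_PFC}{_PFC}{_PFC}"

_CF_PATTERN = Chem.MolFromSmarts(CF_SMARTS)
_C3F6_PATTERN = Chem.MolFromSmarts(C3F6_SMARTS)


def filter_cf(records: Sequence[MoleculeRecord]) -> list[MoleculeRecord]:
    """Keep records with at least one carbon–fluorine bond (order preserved)."""
    return [
        rec for rec in records if mol_from_record(rec).HasSubstructMatch(_CF_PATTERN)
    ]


def filter_c3f6(records: Sequence[MoleculeRecord]) -> list[MoleculeRecord]:
    """Keep records containing a perfluoroalkyl chain of three or more carbons.

    Output is always a subset of :func:`filter_cf` output: three contiguous
    perfluorinated carbons imply at least one C–F bond.
    """
    return [
        rec for rec in records if mol_from_record(rec).HasSubstructMatch(_C3F6_PATTERN)
    ]
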