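"""Binding-affinity tables (kcal/mol) and threshold summaries.

Affinities are docking scores: more negative means stronger predicted
binding.  "Stronger than a threshold" is a strict inequality (affinity
strictly more negative than the threshold).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .chemio import MoleculeRecord
from .errors import DataError, ParameterError

__all__ = [
    "AffinityTable",
    "AffinitySummary",
    "read_affinity_table",
    "write_affinity_table",
    "affinity_summary",
    "affinity_vector",
]

logger = logging.getLogger(__name__)


@dataclass
class AffinityTable:
    """Map (molecule id, target name) -> affinity in kcal/mol."""

    entries: dict[tuple[str, str], float] = field(default_factory=dict)

    def get(self, mol_id: str, target: str) -> float | None:
        return self.entries.get((mol_id, target))

    def for_target(self, target: str) -> dict[str, float]:
        return {mid: a for (mid, t), a in self.entries.items() if t == target}

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class AffinitySummary:
    fraction_stronger: float
    mean: float
    n: int
    threshold: float


def read_affinity_table(path: str | Path) -> AffinityTable:
    """Read a CSV with columns id, target, affinity.

    Duplicate (id, target) keys: last row wins, with a warning.  Non-numeric
    or non-finite affinities raise :class:`DataError` naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"affinity table not found: {path}")
    table = AffinityTable()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"id", "target", "affinity"} <= set(
            reader.fieldnames
        ):
            raise DataError(f"{path}: expected columns id, target, affinity")
        for row_num, row in enumerate(reader, start=1):
            key = ((row["id"] or "").strip(), (row["target"] or "").strip())
            raw = (row["affinity"] or "").strip()
            try:
                value = float(raw)
            except ValueError:
                raise DataError(
                    f"{path}: row {row_num}: non-numeric affinity {raw!r}"
                ) from None
            if not math.isfinite(value):
                raise DataError(f"{path}: row {row_num}: non-finite affinity {raw!r}")
            if key in table.entries:
                logger.warning(
                    "duplicate affinity key %r at row %d: keeping the later value",
                    key,
                    row_num,
                )
            table.entries[key] = value
    return table


def write_affinity_table(table: AffinityTable, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "target", "affinity"])
        for (mol_id, target), value in table.entries.items():
            writer.writerow([mol_id, target, f"{value:.10g}"])
    return path


def affinity_summary(
    table: AffinityTable, target: str, threshold: float = -5.0
) -> AffinitySummary:
    """Fraction of entries strictly below the threshold, plus mean and count."""
    values = list(table.for_target(target).values())
    if not values:
        raise ParameterError(f"no affinity entries for target {target!r}")
    n = len(values)
    stronger = sum(1 for v in values if v < threshold)
    return AffinitySummary(
        fraction_stronger=stronger / n,
        mean=sum(values) / n,
        n=n,
        threshold=threshold,
    )


def affinity_vector(
    records: Sequence[MoleculeRecord], table: AffinityTable, target: str
) -> tuple[list[float], list[bool]]:
    """Per-record affinities for one target.

    Returns (values, present) aligned to ``records``; missing entries carry
    NaN with present=False and are counted in a log message, never imputed.
    """
    values: list[float] = []
    present: list[bool] = []
    missing = 0
    for rec in records:
        value = table.get(rec.id, target)
        if value is None:
            values.append(float("nan"))
            present.append(False)
            missing += 1
        else:
            values.append(value)
            present.append(True)
    if missing:
        logger.info(
            "affinity_vector: %d of %d records missing affinity for %r",
            missing,
            len(records),
            target,
        )
    return values, present
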