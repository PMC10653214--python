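"""Maximum-common-substructure motifs and the bioactive-ratio statistic.

For each high-activity cluster, the maximum common substructure (MCS) of the
cluster's ACTIVE members is extracted as a SMARTS motif; the motif is then
matched dataset-wide and scored by its bioactive ratio: the fraction of
motif-matching, *labeled* molecules that are ACTIVE.  Unlabeled molecules
are excluded from both numerator and denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFMCS

from .chemio import ActivityLabel, MoleculeRecord, mol_from_record
from .embed_cluster import ClusterAssignment
from .errors import ParameterError, PatternError

__all__ = [
    "EMPTY_MOTIF",
    "ESTER_SMARTS",
    "RatioResult",
    "SubstructureReport",
    "find_mcs",
    "match_substructure",
    "bioactive_ratio",
    "cluster_motif_report",
    "detect_ester",
]

logger = logging.getLogger(__name__)

#: Sentinel returned when no common substructure of >= 2 atoms exists.
EMPTY_MOTIF = ""

#: Carboxylic ester (excludes free acids: the single-bonded O must bear a carbon).
ESTER_SMARTS = "[CX3](=O)[OX2][#6]"

_MCS_SAMPLE_CAP = 100


@dataclass
class RatioResult:
    """Counts and ratio for one motif; ratio is NaN when no labeled match exists."""

    n_match: int
    n_match_active: int
    bioactive_ratio: float


@dataclass
class SubstructureReport:
    smarts: str
    n_match: int
    n_match_active: int
    bioactive_ratio: float
    target: str
    source_cluster: int | None = None


def find_mcs(
    molecules: Sequence[MoleculeRecord],
    completion_threshold: float = 0.8,
    timeout: int = 10,
    seed: int = 0,
) -> str:
    """SMARTS of the maximum common substructure of the input molecules.

    ``completion_threshold`` is the fraction of molecules the substructure
    must appear in.  Atoms compare by element; ring bonds only match ring
    bonds (ring *atoms* may match chain atoms, so an exocyclic attachment can
    align with an aliphatic one).  Returns :data:`EMPTY_MOTIF` when nothing
    of >= 2 atoms is shared.  Exact multi-molecule MCS is intractable for
    large inputs, so sets larger than 100 molecules are reduced to a seeded
    random sample.
    """
    if len(molecules) < 2:
        raise ParameterError("find_mcs needs at least 2 molecules")
    if not 0.0 < completion_threshold <= 1.0:
        raise ParameterError(
            f"completion_threshold must lie in (0, 1], got {completion_threshold}"
        )
    mols = [mol_from_record(rec) for rec in molecules]
    if len(mols) > _MCS_SAMPLE_CAP:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(mols), size=_MCS_SAMPLE_CAP, replace=False)
        mols = [mols[i] for i in sorted(idx)]
    params = rdFMCS.MCSParameters()
    params.AtomCompareParameters.RingMatchesRingOnly = False
    params.BondCompareParameters.RingMatchesRingOnly = True
    params.Threshold = completion_threshold
    params.Timeout = timeout
    result = rdFMCS.FindMCS(mols, params)
    if result.numAtoms < 2 or not result.smartsString:
        return EMPTY_MOTIF
    return result.smartsString


def match_substructure(
    records: Sequence[MoleculeRecord], smarts: str
) -> np.ndarray:
    """Boolean mask: mask[i] is True iff molecule i contains the motif."""
    pattern = Chem.MolFromSmarts(smarts)
    if pattern is None:
        raise PatternError(f"invalid SMARTS: {smarts!r}")
    mask = np.zeros(len(records), dtype=bool)
    for i, rec in enumerate(records):
        mask[i] = mol_from_record(rec).HasSubstructMatch(pattern)
    return mask


def bioactive_ratio(
    mask: np.ndarray, labels: Sequence[ActivityLabel]
) -> RatioResult:
    """Fraction of labeled, motif-matching molecules that are ACTIVE.

    UNLABELED entries are excluded from both counts.  With zero labeled
    matches the ratio is NaN (counts are kept).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != len(labels):
        raise ParameterError(
            f"mask length {mask.shape[0]} != labels length {len(labels)}"
        )
    n_match = 0
    n_active = 0
    for hit, label in zip(mask, labels):
        if not hit or label is ActivityLabel.UNLABELED:
            continue
        n_match += 1
        if label is ActivityLabel.ACTIVE:
            n_active += 1
    ratio = n_active / n_match if n_match > 0 else float("nan")
    return RatioResult(n_match=n_match, n_match_active=n_active, bioactive_ratio=ratio)


def cluster_motif_report(
    records: Sequence[MoleculeRecord],
    assignment: ClusterAssignment,
    target: str,
    top_clusters: int = 5,
    completion_threshold: float = 0.8,
    mcs_timeout: int = 10,
    seed: int = 0,
) -> list[SubstructureReport]:
    """Motif reports for the clusters richest in ACTIVE molecules.

    Clusters are ranked by their active fraction among labeled members; for
    each of the ``top_clusters`` best, the MCS of the cluster's ACTIVE
    members is matched dataset-wide and scored.  Clusters with fewer than two
    actives are skipped with a logged notice.  Reports come back sorted by
    bioactive ratio, descending (NaN last).
    """
    labels_vec = np.asarray(assignment.labels)
    if labels_vec.shape[0] != len(records):
        raise ParameterError("cluster assignment does not cover the record list")
    activity = [rec.label_for(target) for rec in records]

    ranked: list[tuple[float, int]] = []
    for c in range(assignment.k):
        member_idx = np.nonzero(labels_vec == c)[0]
        labeled = [
            i for i in member_idx if activity[i] is not ActivityLabel.UNLABELED
        ]
        n_active = sum(1 for i in labeled if activity[i] is ActivityLabel.ACTIVE)
        frac = n_active / len(labeled) if labeled else 0.0
        ranked.append((frac, c))
    ranked.sort(key=lambda t: (-t[0], t[1]))

    reports: list[SubstructureReport] = []
    for frac, c in ranked[:top_clusters]:
        member_idx = np.nonzero(labels_vec == c)[0]
        active_members = [
            records[i] for i in member_idx if activity[i] is ActivityLabel.ACTIVE
        ]
        if len(active_members) < 2:
            logger.info(
                "cluster %d skipped: %d active member(s), need >= 2",
                c,
                len(active_members),
            )
            continue
        smarts = find_mcs(
            active_members,
            completion_threshold=completion_threshold,
            timeout=mcs_timeout,
            seed=seed,
        )
        if smarts == EMPTY_MOTIF:
            logger.info("cluster %d skipped: no common substructure", c)
            continue
        mask = match_substructure(records, smarts)
        ratio = bioactive_ratio(mask, activity)
        reports.append(
            SubstructureReport(
                smarts=smarts,
                n_match=ratio.n_match,
                n_match_active=ratio.n_match_active,
                bioactive_ratio=ratio.bioactive_ratio,
                target=target,
                source_cluster=int(c),
            )
        )
    reports.sort(
        key=lambda r: (
            -(r.bioactive_ratio if r.bioactive_ratio == r.bioactive_ratio else -1.0),
            r.source_cluster if r.source_cluster is not None else 0,
        )
    )
    return reports


_ESTER_PATTERN = Chem.MolFromSmarts(ESTER_SMARTS)


def detect_ester(record: MoleculeRecord) -> bool:
    """True iff the molecule contains a carboxylic ester group."""
    return bool(mol_from_record(record).HasSubstructMatch(_ESTER_PATTERN))
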