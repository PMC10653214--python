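"""Semi-supervised Mahalanobis metric learning from pairwise label constraints.

A linear map ``L`` (d_out x d_in) is learned so that the induced distance
``d(x, y) = ||L (x - y)||_2`` contracts same-labeled pairs and pushes
opposite-labeled pairs beyond a margin.  The implied Mahalanobis matrix
``M = L^T L`` is positive semi-definite by construction.  Training minimizes
the margin-based contrastive loss

    sum_{similar} d^2  +  sum_{dissimilar} max(0, margin - d)^2

by mini-batch gradient descent on ``L``.  Only labeled records contribute
constraints; the learned map is then applied to every record, labeled or
not — that transfer is what makes the procedure semi-supervised.

``L`` is initialized from the top principal components of the descriptor
matrix (falling back to an identity truncation for degenerate data), which
stabilizes early epochs on sparse high-dimensional binary fingerprints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

from .chemio import ActivityLabel, MoleculeRecord
from .errors import (
    DimensionError,
    DivergenceError,
    InsufficientLabelsError,
    ParameterError,
)

__all__ = [
    "Relation",
    "PairConstraint",
    "MetricModel",
    "build_constraints",
    "fit_metric",
    "transform",
    "save_model",
    "load_model",
]


class Relation(Enum):
    SIMILAR = "similar"
    DISSIMILAR = "dissimilar"


@dataclass(frozen=True)
class PairConstraint:
    """An (i, j) pair of record indices with a same/opposite-label relation."""

    i: int
    j: int
    relation: Relation

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ParameterError("pair constraint endpoints must differ")


@dataclass
class MetricModel:
    """Learned linear map defining d(x, y) = ||L (x - y)||."""

    L: np.ndarray
    d_in: int
    d_out: int
    margin: float
    loss_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=np.float64)
        if self.L.shape != (self.d_out, self.d_in):
            raise DimensionError(
                f"L shape {self.L.shape} != (d_out, d_in) = ({self.d_out}, {self.d_in})"
            )

    @property
    def mahalanobis_matrix(self) -> np.ndarray:
        """M = L^T L (symmetric positive semi-definite)."""
        return self.L.T @ self.L

    def distance(self, x: np.ndarray, y: np.ndarray) -> float:
        return float(np.linalg.norm(self.L @ (np.asarray(x) - np.asarray(y))))


def build_constraints(
    records: Sequence[MoleculeRecord],
    target: str,
    max_pairs: int | None = None,
    seed: int = 0,
) -> list[PairConstraint]:
    """Sample a balanced set of SIMILAR/DISSIMILAR pairs among labeled records.

    All pairs are enumerated when they fit within ``max_pairs``; otherwise a
    seeded, balanced subsample (half similar, half dissimilar, capped by
    availability) is drawn.  Requires at least one ACTIVE and one INACTIVE
    labeled record.
    """
    actives = [
        i for i, r in enumerate(records) if r.label_for(target) is ActivityLabel.ACTIVE
    ]
    inactives = [
        i
        for i, r in enumerate(records)
        if r.label_for(target) is ActivityLabel.INACTIVE
    ]
    if not actives or not inactives:
        raise InsufficientLabelsError(
            f"target {target!r}: need >=1 ACTIVE and >=1 INACTIVE labeled record "
            f"(got {len(actives)} active, {len(inactives)} inactive)"
        )

    similar = [
        PairConstraint(i, j, Relation.SIMILAR)
        for group in (actives, inactives)
        for i, j in combinations(group, 2)
    ]
    dissimilar = [
        PairConstraint(i, j, Relation.DISSIMILAR) for i in actives for j in inactives
    ]

    total = len(similar) + len(dissimilar)
    if max_pairs is None or total <= max_pairs:
        return similar + dissimilar

    rng = np.random.default_rng(seed)
    half = max_pairs // 2
    n_sim = min(half, len(similar))
    n_dis = min(max_pairs - n_sim, len(dissimilar))
    if n_dis < max_pairs - n_sim:  # dissimilar exhausted; refill from similar
        n_sim = min(max_pairs - n_dis, len(similar))
    picked_sim = rng.choice(len(similar), size=n_sim, replace=False)
    picked_dis = rng.choice(len(dissimilar), size=n_dis, replace=False)
    return [similar[k] for k in sorted(picked_sim)] + [
        dissimilar[k] for k in sorted(picked_dis)
    ]


def _canonical_order(constraints: Sequence[PairConstraint]) -> list[PairConstraint]:
    # Sort so the fitted model is invariant to the caller's constraint order.
    return sorted(
        constraints, key=lambda c: (min(c.i, c.j), max(c.i, c.j), c.relation.value)
    )


def _pca_init(X: np.ndarray, d_out: int) -> np.ndarray:
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0):
        return np.eye(d_out, X.shape[1])
    try:
        # right singular vectors of the centered matrix = principal axes
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    except np.linalg.LinAlgError:
        return np.eye(d_out, X.shape[1])
    L = Vt[:d_out].copy()
    if L.shape[0] < d_out:  # rank-deficient: pad with identity rows
        pad = np.eye(d_out - L.shape[0], X.shape[1])
        L = np.vstack([L, pad])
    return L


def _full_loss(
    L: np.ndarray,
    diffs: np.ndarray,
    is_similar: np.ndarray,
    margin: float,
) -> float:
    Z = diffs @ L.T
    d = np.linalg.norm(Z, axis=1)
    loss = np.where(is_similar, d**2, np.maximum(0.0, margin - d) ** 2)
    return float(loss.mean())


def fit_metric(
    X: np.ndarray,
    constraints: Sequence[PairConstraint],
    d_out: int = 64,
    margin: float = 1.0,
    learning_rate: float = 0.01,
    epochs: int = 100,
    batch_size: int = 256,
    seed: int = 0,
    init: str = "pca",
) -> MetricModel:
    """Fit the linear metric by mini-batch gradient descent.

    The loss trace records the mean constraint loss before training and after
    each epoch; the returned model is the best iterate seen, so the final
    trace entry never exceeds the first.  Raises :class:`DivergenceError`
    when the loss becomes non-finite (the remedy is a smaller learning rate).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise DimensionError("X must be a 2-D descriptor matrix")
    if epochs < 1:
        raise ParameterError(f"epochs must be >= 1, got {epochs}")
    if not constraints:
        raise ParameterError("at least one pair constraint is required")
    if d_out < 1 or d_out > X.shape[1]:
        raise ParameterError(f"d_out must lie in [1, {X.shape[1]}], got {d_out}")
    n = X.shape[0]
    for c in constraints:
        if not (0 <= c.i < n and 0 <= c.j < n):
            raise DimensionError(f"constraint ({c.i}, {c.j}) outside X rows [0, {n})")

    ordered = _canonical_order(constraints)
    diffs = np.stack([X[c.i] - X[c.j] for c in ordered])
    is_similar = np.array([c.relation is Relation.SIMILAR for c in ordered])

    if init == "pca":
        L = _pca_init(X, d_out)
    elif init == "identity":
        L = np.eye(d_out, X.shape[1])
    else:
        raise ParameterError(f"unknown init {init!r}")

    rng = np.random.default_rng(seed)
    m = len(ordered)
    trace = [_full_loss(L, diffs, is_similar, margin)]
    best_loss = trace[0]
    best_L = L.copy()

    eps = 1e-12
    for _ in range(epochs):
        order = rng.permutation(m)
        for start in range(0, m, batch_size):
            idx = order[start : start + batch_size]
            D = diffs[idx]
            sim = is_similar[idx]
            Z = D @ L.T  # (b, d_out)
            d = np.linalg.norm(Z, axis=1)
            # d(loss)/dZ per pair: similar -> 2 Z; violated dissimilar ->
            # -2 (margin - d) Z / d; satisfied dissimilar -> 0.
            coef = np.where(
                sim,
                2.0,
                np.where(d < margin, -2.0 * (margin - d) / np.maximum(d, eps), 0.0),
            )
            grad = (coef[:, None] * Z).T @ D / len(idx)
            L = L - learning_rate * grad
        loss = _full_loss(L, diffs, is_similar, margin)
        if not np.isfinite(loss):
            raise DivergenceError(
                "training loss became non-finite; reduce learning_rate"
            )
        trace.append(loss)
        if loss < best_loss:
            best_loss = loss
            best_L = L.copy()

    if trace[-1] > best_loss:
        # return the best iterate; close the trace on its loss
        L = best_L
        trace.append(best_loss)
    return MetricModel(
        L=L, d_in=X.shape[1], d_out=d_out, margin=margin, loss_trace=trace
    )


def transform(model: MetricModel, X: np.ndarray) -> np.ndarray:
    """Embed descriptor rows: returns X @ L^T, shape (n, d_out).

    Applies to labeled and unlabeled rows alike.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.d_in:
        raise DimensionError(
            f"X has shape {X.shape}; model expects (*, {model.d_in})"
        )
    return X @ model.L.T


def save_model(model: MetricModel, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "d_in": model.d_in,
        "d_out": model.d_out,
        "margin": model.margin,
        "L": model.L.ravel().tolist(),
        "loss_trace": list(model.loss_trace),
    }
    path.write_text(json.dumps(payload), encoding="utf-8")
    return path


def load_model(path: str | Path) -> MetricModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    L = np.array(payload["L"], dtype=np.float64).reshape(
        payload["d_out"], payload["d_in"]
    )
    return MetricModel(
        L=L,
        d_in=payload["d_in"],
        d_out=payload["d_out"],
        margin=payload["margin"],
        loss_trace=list(payload["loss_trace"]),
    )
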