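"""PCA dimensionality reduction of observation vectors.

Two variants are exposed.  *Average PCA* computes the principal axes of the
six per-tag mean traces, which concentrates the class-discriminative late
component in the first dimension but is limited to ``n_tags - 1`` components.
*Raw PCA* computes the axes of all raw observation vectors; it scales to many
components but extracts the informative directions less efficiently.

Neither variant sees the real/random labels: tag means use only the public
presentation tags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .preprocess import ObservationSet

__all__ = [
    "TagMeans", "ProjectionBasis", "ReducedObservations",
    "tag_means", "average_pca", "raw_pca", "project", "max_rank",
]

#: Relative eigenvalue threshold below which a component counts as null.
RANK_TOL = 1e-10


@dataclass
class TagMeans:
    """Per-tag arithmetic mean observation vectors."""

    means: np.ndarray            # (n_tags, D)
    counts: np.ndarray           # (n_tags,), surviving epochs per tag
    tag_values: np.ndarray       # (n_tags,)


@dataclass
class ProjectionBasis:
    """Orthonormal projection rows R_1..R_{N_d} with their centering vector."""

    components: np.ndarray       # (n_d, D)
    center: np.ndarray           # (D,)
    source: str                  # "average" | "raw"
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)

    @property
    def n_d(self) -> int:
        return self.components.shape[0]

    @property
    def dim(self) -> int:
        return self.components.shape[1]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "components": self.components.tolist(),
                    "center": self.center.tolist(),
                    "source": self.source,
                    "explained_variance": self.explained_variance.tolist(),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "ProjectionBasis":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            components=np.asarray(d["components"]),
            center=np.asarray(d["center"]),
            source=d["source"],
            explained_variance=np.asarray(d["explained_variance"]),
        )


@dataclass
class ReducedObservations:
    """Projected scores: one row per epoch, one column per retained component."""

    scores: np.ndarray           # (n_epochs, n_d)
    tags: np.ndarray
    user_id: int
    basis: ProjectionBasis


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|coefficient| entry positive."""
    out = components.copy()
    for i, row in enumerate(out):
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            out[i] = -row
    return out


def tag_means(obs: ObservationSet, expected_tags=None) -> TagMeans:
    """Arithmetic mean vector of the surviving epochs of each tag.

    ``expected_tags`` asserts that every listed tag still has at least one
    surviving epoch (rejection may otherwise silently empty a class).
    """
    values = np.unique(obs.tags)
    if expected_tags is not None:
        missing = np.setdiff1d(np.asarray(expected_tags), values)
        if missing.size:
            raise ValueError(f"tags {missing.tolist()} have no surviving epochs")
    if values.size == 0:
        raise ValueError("no epochs: cannot compute tag means")
    means = np.empty((values.size, obs.dim))
    counts = np.empty(values.size, dtype=int)
    for i, t in enumerate(values):
        rows = obs.vectors[obs.tags == t]
        if rows.shape[0] == 0:
            raise ValueError(f"tag {t} has no surviving epochs")
        means[i] = rows.mean(axis=0)
        counts[i] = rows.shape[0]
    return TagMeans(means=means, counts=counts, tag_values=values)


def average_pca(means: TagMeans, n_d: int = 5) -> ProjectionBasis:
    """Principal axes of the per-tag mean traces.

    With ``n_tags`` mean vectors at most ``n_tags - 1`` components carry
    nonzero variance; requesting more than the achievable rank is an error.
    """
    rows = means.means
    n_tags = rows.shape[0]
    if n_d > n_tags - 1:
        raise ValueError(f"n_d={n_d} exceeds n_tags-1={n_tags - 1}")
    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(rows)
    ev = pca.explained_variance_
    rank = int(np.sum(ev > RANK_TOL * ev[0])) if ev[0] > 0 else 0
    if n_d > rank:
        raise ValueError(
            f"requested n_d={n_d} but the tag means only support rank {rank}"
        )
    return ProjectionBasis(
        components=_fix_signs(pca.components_[:n_d]),
        center=rows.mean(axis=0),
        source="average",
        explained_variance=ev[:n_d],
    )


def raw_pca(obs: ObservationSet, n_d: int = 5) -> ProjectionBasis:
    """Principal axes of all raw observation vectors (globally centered)."""
    n = obs.n_epochs
    if n_d >= n:
        raise ValueError(f"n_d={n_d} requires more than {n_d} epochs, got {n}")
    pca = PCA(n_components=n_d, svd_solver="full")
    pca.fit(obs.vectors)
    return ProjectionBasis(
        components=_fix_signs(pca.components_),
        center=obs.vectors.mean(axis=0),
        source="raw",
        explained_variance=pca.explained_variance_.copy(),
    )


def max_rank(means: TagMeans) -> int:
    """Number of principal components of the tag means with nonzero eigenvalue.

    A component counts as nonzero when its eigenvalue exceeds ``RANK_TOL``
    times the largest one.
    """
    rows = means.means
    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(rows)
    ev = pca.explained_variance_
    if ev.size == 0 or ev[0] <= 0:
        return 0
    return int(np.sum(ev > RANK_TOL * ev[0]))


def project(obs: ObservationSet, basis: ProjectionBasis) -> ReducedObservations:
    """Scores of the centered observations on the basis rows."""
    if obs.dim != basis.dim:
        raise ValueError(
            f"dimension mismatch: observations have D={obs.dim}, basis D={basis.dim}"
        )
    scores = (obs.vectors - basis.center) @ basis.components.T
    return ReducedObservations(
        scores=scores, tags=obs.tags.copy(), user_id=obs.user_id, basis=basis
    )
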