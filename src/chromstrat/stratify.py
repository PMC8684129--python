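"""Embed tumors from the rank matrix and assign chromatin groups.

The embedding is a 2-D UMAP of the samples (columns of the rank matrix)
with Euclidean distance on rank columns; any callable mapping samples to
2-D may be substituted for UMAP through the ``reducer`` argument. Group
assignment formalizes the visual delineation of embedding clusters as
k-means on the embedding coordinates with multiple restarts and a fixed
seed; labels are re-indexed 1..k by decreasing separation of the cluster
centroid along embedding dimension 2, where most chromatin differences
concentrate.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .types import RankMatrix

Reducer = Callable[[np.ndarray, int, int], np.ndarray]


@dataclass
class Embedding:
    """2-D coordinates per sample plus the seed that produced them."""

    sample_ids: tuple[str, ...]
    coordinates: np.ndarray  # shape (n_samples, 2)
    seed: int

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.sample_ids), 2):
            raise ValueError("coordinates must be one 2-D row per sample")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("embedding coordinates must be finite")


@dataclass
class GroupAssignment:
    """Mapping sample_id -> chromatin group in 1..k."""

    mapping: dict[str, int]

    @property
    def k(self) -> int:
        return max(self.mapping.values())

    def labels(self, sample_ids) -> np.ndarray:
        return np.array([self.mapping[s] for s in sample_ids], dtype=int)

    def members(self, group: int) -> list[str]:
        return [s for s, g in self.mapping.items() if g == group]

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for g in self.mapping.values():
            out[g] = out.get(g, 0) + 1
        return dict(sorted(out.items()))


def _umap_reducer(x: np.ndarray, n_neighbors: int, seed: int) -> np.ndarray:
    import umap  # deferred: numba compilation is expensive

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*n_jobs value 1.*")
        warnings.filterwarnings("ignore", message=".*random_state.*")
        reducer = umap.UMAP(
            n_neighbors=n_neighbors, n_components=2, min_dist=0.1, random_state=seed
        )
        return np.asarray(reducer.fit_transform(x), dtype=float)


def embed(
    ranks: RankMatrix,
    n_neighbors: int = 10,
    seed: int = 0,
    reducer: Reducer | None = None,
) -> Embedding:
    """2-D neighborhood embedding of the samples of a rank matrix.

    Deterministic given ``seed``. Requires at least ``n_neighbors + 1``
    samples.
    """
    x = ranks.data.to_numpy(dtype=float).T
    n = x.shape[0]
    if n < n_neighbors + 1:
        raise ValueError(f"need at least n_neighbors+1={n_neighbors + 1} samples, got {n}")
    coords = (_umap_reducer if reducer is None else reducer)(x, n_neighbors, seed)
    return Embedding(tuple(ranks.sample_ids), np.asarray(coords, dtype=float), seed)


def assign_groups(embedding: Embedding, k: int = 3, seed: int = 0) -> GroupAssignment:
    """Partition embedding coordinates into k chromatin groups.

    Centroid-based clustering (k-means, 10 restarts, fixed seed); group
    labels are ordered by decreasing centroid separation along embedding
    dimension 2. ``k`` must be >= 2 and <= the number of samples.
    """
    from sklearn.cluster import KMeans

    n = len(embedding.sample_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples ({n})")
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore")  # duplicate points trigger convergence warnings
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(embedding.coordinates)
    raw = km.labels_
    present = np.unique(raw)
    cent2 = {c: float(embedding.coordinates[raw == c, 1].mean()) for c in present}
    seps = {}
    for c in present:
        others = [cent2[o] for o in present if o != c]
        seps[c] = abs(cent2[c] - float(np.mean(others))) if others else 0.0
    order = sorted(present, key=lambda c: (-seps[c], c))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    mapping = {s: relabel[c] for s, c in zip(embedding.sample_ids, raw)}
    return GroupAssignment(mapping)
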