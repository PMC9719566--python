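"""Extraction and k-means summarisation of recurrent activation maps.

Each (image, channel) spatial hidden-state map of the last cell at a chosen
time step is one clustering point; maps from one class are clustered
together (k = 10 in the study) and the centroids act as representative
activation patterns. Clustering is plain Lloyd iteration with greedy
farthest-point seeding, run to assignment convergence with a recorded,
non-increasing objective trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidDataError, InvalidSpecError
from .stimuli import IMAGE_SIZE, DatasetFamily


@dataclass
class ActivationMapSet:
    """Spatial activation maps with full provenance per map."""

    maps: np.ndarray  # (n_maps, 20, 20) float32
    image_id: np.ndarray
    channel_id: np.ndarray
    timestep: int
    class_label: int
    family: str = ""

    def __len__(self) -> int:
        return len(self.maps)


@dataclass
class CentroidSet:
    """k centroid maps, the hard assignment of every map, and the objective
    (within-cluster sum of squares) trace across Lloyd iterations."""

    centroids: np.ndarray  # (k, 20, 20)
    assignments: np.ndarray  # (n_maps,)
    inertia: float
    objective_trace: np.ndarray

    @property
    def k(self) -> int:
        return len(self.centroids)

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"iteration": np.arange(len(self.objective_trace)),
             "objective": self.objective_trace}
        )


def extract_activation_maps(
    model, family: DatasetFamily, timestep: int, class_filter: int
) -> ActivationMapSet:
    """Last-cell hidden-state maps at ``timestep`` for one class of a
    family: one map per (image, channel) pair."""
    if timestep < 1 or timestep > model.unroll_steps:
        raise InvalidSpecError(
            f"timestep must lie in [1, {model.unroll_steps}], got {timestep}"
        )
    mask = family.labels == class_filter
    if not np.any(mask):
        raise InvalidDataError(f"family holds no class-{class_filter} images")
    images = family.images[mask]
    hidden = model.hidden_states(images, steps=[timestep], cell=-1)[:, 0]
    n, c = hidden.shape[:2]
    maps = hidden.reshape(n * c, IMAGE_SIZE, IMAGE_SIZE)
    return ActivationMapSet(
        maps=maps,
        image_id=np.repeat(np.arange(n), c),
        channel_id=np.tile(np.arange(c), n),
        timestep=timestep,
        class_label=class_filter,
        family=family.spec.name,
    )


def _farthest_point_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy farthest-point seeding from a seeded random start."""
    centers = [X[rng.integers(len(X))]]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for _ in range(1, k):
        centers.append(X[int(np.argmax(d2))])
        d2 = np.minimum(d2, np.sum((X - centers[-1]) ** 2, axis=1))
    return np.stack(centers)


def cluster_activation_maps(
    maps: ActivationMapSet | np.ndarray,
    k: int = 10,
    seed: int = 0,
    max_iter: int = 300,
) -> CentroidSet:
    """Lloyd k-means over flattened activation maps.

    Assignment ties break toward the lowest centroid index; empty clusters
    keep their previous centroid. Converges when assignments stabilise; the
    objective trace is non-increasing by construction of the two Lloyd
    half-steps.
    """
    arr = maps.maps if isinstance(maps, ActivationMapSet) else np.asarray(maps)
    X_in = arr.reshape(len(arr), -1).astype(np.float64)
    if len(X_in) < k:
        raise InvalidDataError(f"need at least k={k} maps, got {len(X_in)}")
    # cluster in canonical (lexicographic) row order so the result is
    # invariant to how the maps were ordered by the caller
    order = np.lexsort(X_in.T[::-1])
    X = X_in[order]
    rng = np.random.default_rng(seed)
    centers = _farthest_point_init(X, k, rng)
    prev_assign = None
    trace = []
    for _ in range(max_iter):
        # argmin returns the lowest index on ties
        d2 = (
            np.sum(X**2, axis=1)[:, None]
            - 2.0 * X @ centers.T
            + np.sum(centers**2, axis=1)[None, :]
        )
        assign = np.argmin(d2, axis=1)
        trace.append(float(np.sum((X - centers[assign]) ** 2)))
        if prev_assign is not None and np.array_equal(assign, prev_assign):
            break
        prev_assign = assign
        for j in range(k):
            sel = assign == j
            if np.any(sel):
                centers[j] = X[sel].mean(axis=0)
    inertia = float(np.sum((X - centers[assign]) ** 2))
    assign_out = np.empty_like(assign)
    assign_out[order] = assign
    side = int(np.sqrt(X.shape[1]))
    return CentroidSet(
        centroids=centers.reshape(k, side, side),
        assignments=assign_out,
        inertia=inertia,
        objective_trace=np.asarray(trace),
    )


def midline_activation(centroids: np.ndarray) -> float:
    """Mean activation over the two midline columns (9 and 10), averaged
    across centroids — the quantity that grows for symmetric-class
    centroids as time steps progress."""
    c = np.asarray(centroids)
    return float(c[..., 9:11].mean())
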