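"""Two-stage decomposition of configurational space with per-cluster errors.

Stage 1 groups frames by *structure*: agglomerative clustering (Ward
linkage, Euclidean metric) on the vector of upper-triangle pairwise
interatomic distances of each frame. Stage 2 splits each structural group
by *energetics*: KMeans on the group's reference energies, with the
sub-cluster budget apportioned to groups proportionally to their size
(largest-remainder rounding, every group keeps at least one cluster), for
a requested total of 40 clusters by default.

The distance descriptor is invariant under rigid rotations and
translations, so structurally identical frames land in the same group
regardless of their global placement. Atoms are labeled: descriptor entries
follow the fixed atom-index order, never a sorted order.

For trajectories beyond ``max_exact_frames`` (default 5000) stage 1 runs on
a seeded uniform subsample and the remaining frames are assigned to the
nearest structural centroid, since agglomerative clustering scales
quadratically in frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cluster import AgglomerativeClustering, KMeans

from .metrics import ErrorTable
from .trajio import ConfigurationSet, SubsetView

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "distance_descriptor",
    "compute_descriptors",
    "cluster_configurations",
    "cluster_error_profile",
    "cluster_representatives",
]


@dataclass
class ClusterAssignment:
    """Frame-to-cluster mapping with per-cluster error summaries.

    ``labels`` are final cluster ids in ``[0, n_total)``;
    ``structural_labels`` the stage-1 ids in ``[0, n_structural)``.
    ``summaries[c]`` holds ``{"size", "force_mae", "energy_mae"}`` for
    cluster ``c`` (energy_mae is None when no energy errors exist).
    """

    labels: np.ndarray
    structural_labels: np.ndarray
    n_structural: int
    n_total: int
    summaries: list[dict]
    descriptors: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        sizes = np.bincount(self.labels, minlength=self.n_total)
        if sizes.sum() != self.labels.size:
            raise ValueError("cluster sizes must sum to n_frames")
        if np.any(sizes == 0):
            raise ValueError("every cluster id must be used")

    @property
    def n_frames(self) -> int:
        return int(self.labels.size)

    def frames_of(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def distance_descriptor(frame_positions: np.ndarray) -> np.ndarray:
    """Upper-triangle pairwise interatomic distances of one frame, Å.

    Length ``n_atoms * (n_atoms - 1) / 2``, in the fixed atom-index order
    of :func:`scipy.spatial.distance.pdist`.
    """
    pos = np.asarray(frame_positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError("frame positions must be (n_atoms, 3)")
    if pos.shape[0] < 2:
        raise ValueError("distance descriptor needs at least 2 atoms")
    return pdist(pos)


def compute_descriptors(ds: ConfigurationSet, inverse: bool = False) -> np.ndarray:
    """Descriptors for all frames; optionally inverse distances (1/d)."""
    desc = np.stack([distance_descriptor(ds.positions[f]) for f in range(ds.n_frames)])
    return 1.0 / desc if inverse else desc


def _apportion(sizes: np.ndarray, total: int, capacities: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` among groups.

    Every group gets at least 1; no group exceeds its capacity (its number
    of splittable distinct values). Deterministic tie-breaks by group index.
    """
    g = sizes.size
    alloc = np.ones(g, dtype=int)
    capacities = np.maximum(capacities, 1)
    remaining = total - g
    if remaining <= 0:
        return alloc
    quotas = remaining * sizes / sizes.sum()
    extra = np.floor(quotas).astype(int)
    extra = np.minimum(extra, capacities - alloc)
    remainders = quotas - np.floor(quotas)
    leftover = remaining - extra.sum()
    # hand out leftover units to the largest remainders with spare capacity
    order = np.lexsort((np.arange(g), -remainders))
    while leftover > 0:
        progressed = False
        for i in order:
            if leftover == 0:
                break
            if alloc[i] + extra[i] < capacities[i]:
                extra[i] += 1
                leftover -= 1
                progressed = True
        if not progressed:  # all groups at capacity
            break
    return alloc + extra


def cluster_configurations(
    ds: ConfigurationSet,
    errors: ErrorTable | None = None,
    n_total: int = 40,
    n_structural: int = 10,
    seed: int = 0,
    inverse_distances: bool = False,
    max_exact_frames: int = 5000,
    descriptors: np.ndarray | None = None,
) -> ClusterAssignment:
    """Run the two-stage structural/energetic clustering.

    Parameters
    ----------
    ds : ConfigurationSet
        Must carry reference energies (stage 2 clusters on them).
    errors : ErrorTable, optional
        Supplies the per-cluster force/energy error summaries.
    n_total, n_structural : int
        Final cluster count (default 40) and stage-1 group count
        (default 10); ``n_structural <= n_total``.
    seed : int
        Fixes KMeans initialization and the large-set subsample.
    descriptors : array, optional
        Precomputed frame descriptors (reused across models for
        comparability).
    """
    if ds.energies is None:
        raise ValueError("clustering requires reference energies")
    if n_total < 1 or n_structural < 1:
        raise ValueError("cluster counts must be positive")
    if n_structural > n_total:
        raise ValueError("n_structural must not exceed n_total")
    if errors is not None and errors.n_frames != ds.n_frames:
        raise ValueError("error table is not aligned with the dataset")

    if descriptors is None:
        descriptors = compute_descriptors(ds, inverse=inverse_distances)

    n_frames = ds.n_frames
    n_distinct = np.unique(descriptors, axis=0).shape[0]
    if n_distinct < n_total:
        logger.warning(
            "only %d distinct frames; reducing requested %d clusters",
            n_distinct,
            n_total,
        )
        n_total = n_distinct
        n_structural = min(n_structural, n_total)

    # --- stage 1: structure ------------------------------------------------
    if n_structural == 1:
        structural = np.zeros(n_frames, dtype=int)
    elif n_frames > max_exact_frames:
        rng = np.random.default_rng(seed)
        sample = np.sort(rng.choice(n_frames, size=max_exact_frames, replace=False))
        agg = AgglomerativeClustering(n_clusters=n_structural, linkage="ward")
        sample_labels = agg.fit_predict(descriptors[sample])
        centroids = np.stack(
            [descriptors[sample][sample_labels == g].mean(axis=0)
             for g in range(n_structural)]
        )
        d2 = ((descriptors[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        structural = np.argmin(d2, axis=1)
        structural[sample] = sample_labels
        # drop groups emptied by the nearest-centroid assignment
        used = np.unique(structural)
        remap = {g: i for i, g in enumerate(used)}
        structural = np.array([remap[g] for g in structural])
        n_structural = used.size
    else:
        agg = AgglomerativeClustering(n_clusters=n_structural, linkage="ward")
        structural = agg.fit_predict(descriptors)

    # --- stage 2: energetics ----------------------------------------------
    sizes = np.bincount(structural, minlength=n_structural)
    capacities = np.array(
        [
            np.unique(ds.energies[structural == g]).size
            for g in range(n_structural)
        ]
    )
    budget = _apportion(sizes, n_total, capacities)

    labels = np.empty(n_frames, dtype=int)
    next_id = 0
    for g in range(n_structural):
        members = np.flatnonzero(structural == g)
        k = min(int(budget[g]), int(np.unique(ds.energies[members]).size))
        if k <= 1 or members.size <= 1:
            labels[members] = next_id
            next_id += 1
            continue
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        sub = km.fit_predict(ds.energies[members].reshape(-1, 1))
        labels[members] = next_id + sub
        next_id += k
    # compact label ids in case a KMeans run returned fewer clusters
    used = np.unique(labels)
    remap = {c: i for i, c in enumerate(used)}
    labels = np.array([remap[c] for c in labels])
    n_total_actual = used.size

    summaries = _summarize(labels, n_total_actual, errors)
    return ClusterAssignment(
        labels=labels,
        structural_labels=structural,
        n_structural=n_structural,
        n_total=n_total_actual,
        summaries=summaries,
        descriptors=descriptors,
    )


def _summarize(
    labels: np.ndarray, n_total: int, errors: ErrorTable | None
) -> list[dict]:
    summaries = []
    for c in range(n_total):
        members = np.flatnonzero(labels == c)
        entry: dict = {"size": int(members.size), "force_mae": None, "energy_mae": None}
        if errors is not None:
            entry["force_mae"] = float(errors.atom_errors[members].mean())
            if errors.energy_errors is not None:
                entry["energy_mae"] = float(
                    np.abs(errors.energy_errors[members]).mean()
                )
        summaries.append(entry)
    return summaries


def cluster_error_profile(
    assignment: ClusterAssignment, metric: str = "force_mae"
) -> list[tuple[int, int, float]]:
    """Per-cluster (id, size, value) triples in ascending error order.

    Stable: ties are broken by cluster id.
    """
    if metric not in ("force_mae", "energy_mae"):
        raise ValueError(f"unknown metric {metric!r}")
    rows = []
    for c, s in enumerate(assignment.summaries):
        if s[metric] is None:
            raise ValueError(f"summaries carry no {metric} values")
        rows.append((c, s["size"], float(s[metric])))
    rows.sort(key=lambda r: (r[2], r[0]))
    return rows


def cluster_representatives(
    assignment: ClusterAssignment, ds: ConfigurationSet, k: int = 1
) -> dict[int, SubsetView]:
    """The ``k`` frames of each cluster nearest its descriptor centroid.

    Deterministic: Euclidean distance to the structural-descriptor
    centroid, ties broken by frame index. Clusters smaller than ``k``
    return all their frames.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    desc = assignment.descriptors
    if desc is None:
        desc = compute_descriptors(ds)
    out: dict[int, SubsetView] = {}
    for c in range(assignment.n_total):
        members = assignment.frames_of(c)
        centroid = desc[members].mean(axis=0)
        dist = np.linalg.norm(desc[members] - centroid, axis=1)
        order = np.lexsort((members, dist))
        chosen = np.sort(members[order[: min(k, members.size)]])
        out[c] = SubsetView(ds, chosen, label=f"cluster{c}_rep")
    return out
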