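"""Expression-profile clustering: shape-based, identity-based, and k-means.

Shape clustering groups probes by the successive-difference vector of their
bin sequences, so membership is invariant to any vertical shift of a whole
trajectory.  Identity clustering groups by the exact bin sequence and
therefore refines the shape partition.  k-means runs on the raw
(un-discretized) aggregated profiles under Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

import numpy as np
from sklearn.cluster import kmeans_plusplus

from .preprocess import AggregatedDataset, DiscretizedTrajectorySet

GroupKey = Hashable


@dataclass(eq=True)
class Partition:
    """Disjoint probe groups whose union is the clustered universe."""

    groups: dict[GroupKey, frozenset[str]]
    method: str
    params: dict = field(default_factory=dict)

    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.groups.values():
            out |= members
        return frozenset(out)

    def group_of(self, probe: str) -> GroupKey:
        for key, members in self.groups.items():
            if probe in members:
                return key
        raise KeyError(f"probe '{probe}' not in any group")

    def labels_for(self, probes: list[str]) -> list[int]:
        """Dense integer labels (by sorted group key repr) for external scoring."""
        order = {key: i for i, (key, _) in enumerate(self.sorted_groups())}
        return [order[self.group_of(p)] for p in probes]

    def sorted_groups(self) -> list[tuple[GroupKey, frozenset[str]]]:
        return sorted(self.groups.items(), key=lambda kv: repr(kv[0]))

    def refines(self, coarser: "Partition") -> bool:
        """True if every group here is contained in one group of ``coarser``."""
        for members in self.groups.values():
            if not any(members <= other for other in coarser.groups.values()):
                return False
        return True


def delta_vector(bins: np.ndarray) -> tuple[int, ...]:
    """Successive bin differences ``(b_2 - b_1, ..., b_N - b_{N-1})``."""
    arr = np.asarray(bins, dtype=int)
    return tuple(int(d) for d in np.diff(arr))


def cluster_by_shape(dset: DiscretizedTrajectorySet) -> Partition:
    """Group probes whose trajectories share the same shape.

    The group key is the delta vector of bin indices, so two trajectories at
    different overall expression levels but with identical per-transition
    movement land in the same group.
    """
    if dset.n_timepoints < 2:
        raise ValueError("shape clustering needs at least 2 time points")
    groups: dict[GroupKey, set[str]] = {}
    for probe, row in zip(dset.probe_ids, dset.trajectories):
        groups.setdefault(delta_vector(row), set()).add(probe)
    return Partition(
        groups={k: frozenset(v) for k, v in groups.items()},
        method="shape",
        params={"bin_width": dset.bin_width},
    )


def cluster_by_identity(dset: DiscretizedTrajectorySet) -> Partition:
    """Group probes with bin-for-bin identical trajectories."""
    groups: dict[GroupKey, set[str]] = {}
    for probe, row in zip(dset.probe_ids, dset.trajectories):
        groups.setdefault(tuple(int(b) for b in row), set()).add(probe)
    return Partition(
        groups={k: frozenset(v) for k, v in groups.items()},
        method="identity",
        params={"bin_width": dset.bin_width},
    )


def _lloyd(
    X: np.ndarray, centers: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """Plain Lloyd iterations; returns labels, centers, WCSS and its history."""
    n, _ = X.shape
    k = centers.shape[0]
    history: list[float] = []
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        # repair empty clusters: move their centroid onto the point farthest
        # from its currently assigned centroid
        for c in range(k):
            if not (labels == c).any():
                worst = int(d2[np.arange(n), labels].argmax())
                centers[c] = X[worst]
                labels[worst] = c
                d2[:, c] = ((X - centers[c]) ** 2).sum(axis=1)
                labels = d2.argmin(axis=1)
        wcss = float(d2[np.arange(n), labels].sum())
        if history and history[-1] < wcss - 1e-9:
            raise AssertionError("WCSS increased across a Lloyd iteration")
        history.append(wcss)
        new_centers = np.vstack(
            [X[labels == c].mean(axis=0) for c in range(k)]
        )
        shift = float(np.abs(new_centers - centers).max())
        centers = new_centers
        if shift <= tol:
            break
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    wcss = float(d2[np.arange(len(X)), labels].sum())
    history.append(wcss)
    return labels, centers, wcss, history


def kmeans_profiles(
    agg: AggregatedDataset,
    k: int,
    seed: int,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> Partition:
    """Lloyd's k-means on raw aggregated profiles, Euclidean distance.

    Runs ``n_init`` k-means++ restarts from a seeded generator and keeps the
    solution with the lowest within-cluster sum of squares.  Missing cells
    are a hard error: exclude those probes first (``discretize`` reports
    them).  Fixed ``seed`` gives bit-identical partitions across runs.
    """
    n = len(agg.probe_ids)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} probes available")
    if np.isnan(agg.values).any():
        bad = [p for p, row in zip(agg.probe_ids, agg.values) if np.isnan(row).any()]
        raise ValueError(
            f"{len(bad)} probes have missing cells (e.g. {bad[0]}); "
            "exclude them before clustering (see the discretization exclusion list)"
        )
    X = np.asarray(agg.values, dtype=float)
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_init):
        init_seed = int(rng.integers(0, 2**31 - 1))
        centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=init_seed)
        labels, centers, wcss, _ = _lloyd(X, centers.copy(), max_iter, tol)
        if best is None or wcss < best[0]:
            best = (wcss, labels, centers)
    assert best is not None
    wcss, labels, centers = best
    groups = {
        int(c): frozenset(p for p, l in zip(agg.probe_ids, labels) if l == c)
        for c in range(k)
    }
    return Partition(
        groups=groups,
        method="kmeans",
        params={
            "k": k,
            "seed": seed,
            "n_init": n_init,
            "max_iter": max_iter,
            "tol": tol,
            "wcss": wcss,
            "centroids": [[float(v) for v in row] for row in centers],
        },
    )
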