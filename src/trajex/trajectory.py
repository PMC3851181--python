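"""The discretized trajectory graph: a prefix tree over bin sequences.

Nodes are keyed by the bin-sequence *prefix* ``(b_1, ..., b_t)`` rather than
the bare ``(t, bin)`` pair, so every non-root node has exactly one parent
even when two histories converge on the same bin.  The flat ``(t, bin)``
grouping is available as a derived query (:func:`node_probes`).

Time indices are 0-based throughout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .preprocess import DiscretizedTrajectorySet

Prefix = tuple[int, ...]


@dataclass(eq=True)
class TrajectoryGraph:
    """Prefix tree of discretized trajectories with probe memberships."""

    n_timepoints: int
    node_members: dict[Prefix, frozenset[str]]
    children: dict[Prefix, list[Prefix]] = field(default_factory=dict)
    level_index: dict[int, list[Prefix]] = field(default_factory=dict)

    @classmethod
    def from_node_members(
        cls, node_members: dict[Prefix, frozenset[str]], n_timepoints: int
    ) -> "TrajectoryGraph":
        graph = cls(n_timepoints=n_timepoints, node_members=dict(node_members))
        graph._reindex()
        return graph

    def _reindex(self) -> None:
        self.children = {}
        self.level_index = {}
        for prefix in self.node_members:
            t = len(prefix) - 1
            self.level_index.setdefault(t, []).append(prefix)
            if t > 0:
                self.children.setdefault(prefix[:-1], []).append(prefix)
        # deterministic export order: bin descending (high expression on top)
        for t in self.level_index:
            self.level_index[t].sort(key=lambda p: (tuple(-b for b in p),))
        for parent in self.children:
            self.children[parent].sort(key=lambda p: -p[-1])

    def parent(self, prefix: Prefix) -> Prefix | None:
        return prefix[:-1] if len(prefix) > 1 else None

    def nodes_at(self, t: int) -> list[Prefix]:
        return list(self.level_index.get(t, []))

    def sorted_edges(self) -> list[tuple[Prefix, Prefix]]:
        edges: list[tuple[Prefix, Prefix]] = []
        for t in sorted(self.level_index):
            for prefix in self.level_index[t]:
                for child in self.children.get(prefix, []):
                    edges.append((prefix, child))
        return edges


def ordered_nodes(graph: TrajectoryGraph) -> list[Prefix]:
    """All nodes ordered by time point, then bin descending."""
    out: list[Prefix] = []
    for t in sorted(graph.level_index):
        out.extend(graph.level_index[t])
    return out


def build_trajectory_graph(dset: DiscretizedTrajectorySet) -> TrajectoryGraph:
    """Group probes by every prefix of their bin sequences.

    At each time point the level's member sets partition the probe universe,
    and each node's member set is the union of its children's.
    """
    if not dset.probe_ids:
        raise ValueError("cannot build a trajectory graph from an empty set")
    members: dict[Prefix, set[str]] = {}
    for probe, row in zip(dset.probe_ids, dset.trajectories):
        bins = tuple(int(b) for b in row)
        for t in range(len(bins)):
            members.setdefault(bins[: t + 1], set()).add(probe)
    return TrajectoryGraph.from_node_members(
        {k: frozenset(v) for k, v in members.items()}, n_timepoints=dset.n_timepoints
    )


def node_probes(graph: TrajectoryGraph, t: int, b: int) -> frozenset[str]:
    """Probes occupying bin ``b`` at time point ``t`` (the flat node view).

    Union of the members of every level-``t`` prefix ending in ``b``; an
    unoccupied ``(t, b)`` yields the empty set.
    """
    if not 0 <= t < graph.n_timepoints:
        raise ValueError(f"time index {t} out of range [0, {graph.n_timepoints})")
    hit: set[str] = set()
    for prefix in graph.nodes_at(t):
        if prefix[-1] == b:
            hit |= graph.node_members[prefix]
    return frozenset(hit)


def probe_trajectory(dset: DiscretizedTrajectorySet, probe: str) -> tuple[int, ...]:
    """The full bin sequence of one probe; unknown probes are an error."""
    return dset.trajectory(probe)


def write_edge_list(graph: TrajectoryGraph, path: str | Path) -> None:
    """Plain TSV edge list (parent, child, child bin, members) for viewers."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["parent", "child", "t", "bin", "n_members"])
        for parent, child in graph.sorted_edges():
            writer.writerow(
                [
                    "/".join(map(str, parent)),
                    "/".join(map(str, child)),
                    len(child) - 1,
                    child[-1],
                    len(graph.node_members[child]),
                ]
            )
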