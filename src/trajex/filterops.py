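"""Shape-based trajectory filtering, inverse search, and selection algebra.

A criterion constrains each transition (time point relative to the previous
one) of the discretized trajectory.  All thresholds are integer bin deltas;
``bins_for_delta`` converts an expression-unit threshold to bins.

Criterion syntax (CLI/config): comma-separated transition specs, e.g.
``any,any,any,down:1`` = down by at least one bin at the final transition.
Each spec is ``direction[:min_magnitude[:max_magnitude]]`` with direction
one of ``up``, ``down``, ``same``, ``any``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .cluster import delta_vector
from .preprocess import DiscretizedTrajectorySet

DIRECTIONS = ("up", "down", "same", "any")


@dataclass(frozen=True)
class TransitionSpec:
    """Predicate on one signed bin delta."""

    direction: str = "any"
    min_delta: int | None = None  # inclusive signed lower bound
    max_delta: int | None = None  # inclusive signed upper bound

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if (
            self.min_delta is not None
            and self.max_delta is not None
            and self.min_delta > self.max_delta
        ):
            raise ValueError("min_delta must be <= max_delta")
        if self.direction == "same" and (
            (self.min_delta not in (None, 0)) or (self.max_delta not in (None, 0))
        ):
            raise ValueError("direction 'same' forces delta 0")

    def matches(self, delta: int) -> bool:
        if self.direction == "up" and delta < 1:
            return False
        if self.direction == "down" and delta > -1:
            return False
        if self.direction == "same" and delta != 0:
            return False
        if self.min_delta is not None and delta < self.min_delta:
            return False
        if self.max_delta is not None and delta > self.max_delta:
            return False
        return True


@dataclass(frozen=True)
class ShapeCriterion:
    """One :class:`TransitionSpec` per transition, applied conjunctively."""

    transitions: tuple[TransitionSpec, ...]

    def __len__(self) -> int:
        return len(self.transitions)

    def matches(self, deltas: Sequence[int]) -> bool:
        if len(deltas) != len(self.transitions):
            raise ValueError(
                f"criterion has {len(self.transitions)} transitions, "
                f"trajectory has {len(deltas)}"
            )
        return all(spec.matches(d) for spec, d in zip(self.transitions, deltas))


def parse_criterion(text: str) -> ShapeCriterion:
    """Parse ``"any,up:2,down:1:3"`` into a :class:`ShapeCriterion`.

    Magnitudes are positive bin counts; for ``down`` they are mirrored onto
    the negative axis, so ``down:1:3`` means a delta in ``[-3, -1]``.
    """
    specs: list[TransitionSpec] = []
    for token in text.split(","):
        parts = token.strip().split(":")
        direction = parts[0].lower()
        if direction not in DIRECTIONS:
            raise ValueError(f"bad transition spec '{token}'")
        mags = [int(p) for p in parts[1:3]]
        if any(m < 0 for m in mags):
            raise ValueError(f"magnitudes must be non-negative in '{token}'")
        lo = mags[0] if mags else None
        hi = mags[1] if len(mags) > 1 else None
        if direction == "down":
            specs.append(
                TransitionSpec(
                    "down",
                    min_delta=-hi if hi is not None else None,
                    max_delta=-lo if lo is not None else None,
                )
            )
        elif direction == "up":
            specs.append(TransitionSpec("up", min_delta=lo, max_delta=hi))
        elif direction == "same":
            if mags and any(m != 0 for m in mags):
                raise ValueError("'same' takes no magnitude")
            specs.append(TransitionSpec("same"))
        else:  # any
            if mags:
                raise ValueError(
                    "'any' takes no magnitude; use up/down for signed bounds"
                )
            specs.append(TransitionSpec("any"))
    return ShapeCriterion(tuple(specs))


def bins_for_delta(x: float, w: float) -> int:
    """Smallest bin count whose span covers an expression-unit change ``x``."""
    if w <= 0:
        raise ValueError("bin width must be > 0")
    return math.ceil(x / w)


def filter_by_shape(
    dset: DiscretizedTrajectorySet,
    crit: ShapeCriterion,
    scope: Iterable[str] | None = None,
) -> set[str]:
    """Probes in ``scope`` whose delta vector satisfies every transition spec."""
    n_trans = dset.n_timepoints - 1
    if len(crit) != n_trans:
        raise ValueError(
            f"criterion length {len(crit)} != {n_trans} transitions"
        )
    scope_set = set(dset.probe_ids) if scope is None else set(scope)
    out: set[str] = set()
    for probe, row in zip(dset.probe_ids, dset.trajectories):
        if probe in scope_set and crit.matches(delta_vector(row)):
            out.add(probe)
    return out


def find_inverse(
    dset: DiscretizedTrajectorySet,
    reference: str | Sequence[int],
    scope: Iterable[str] | None = None,
) -> set[str]:
    """Probes whose shape is the element-wise negation of the reference shape.

    ``reference`` is a probe ID (its delta vector is looked up) or an explicit
    delta vector.  A constant reference is its own negation, so it matches
    all constant trajectories.
    """
    if isinstance(reference, str):
        target = tuple(-d for d in delta_vector(dset.trajectory(reference)))
    else:
        target = tuple(-int(d) for d in reference)
    if len(target) != dset.n_timepoints - 1:
        raise ValueError("reference delta vector length mismatch")
    scope_set = set(dset.probe_ids) if scope is None else set(scope)
    return {
        probe
        for probe, row in zip(dset.probe_ids, dset.trajectories)
        if probe in scope_set and delta_vector(row) == target
    }


def apply_selection(
    universe: Iterable[str],
    include: Sequence[str],
    exclude: Sequence[str],
    sets: Mapping[str, Iterable[str]],
) -> set[str]:
    """``(universe ∩ union(include)) \\ union(exclude)`` over named sets.

    An empty include list selects the whole universe.  Unknown set names are
    an error.
    """
    universe_set = set(universe)
    for name in list(include) + list(exclude):
        if name not in sets:
            raise KeyError(f"unknown set name '{name}'")
    if include:
        kept: set[str] = set()
        for name in include:
            kept |= set(sets[name])
        kept &= universe_set
    else:
        kept = set(universe_set)
    for name in exclude:
        kept -= set(sets[name])
    return kept
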