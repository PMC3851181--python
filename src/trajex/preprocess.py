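"""Temporal aggregation and equi-width trajectory discretization.

Bin convention: half-open intervals ``[b*w, (b+1)*w)`` with ``b = floor(e/w)``;
exact boundary values belong to the upper bin.  Values within ``1e-9 * w``
below a boundary are snapped up before flooring to protect boundary cases
from floating-point representation error.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .dataio import ExpressionDataset, LoadReport, ValidationError

#: relative slack (in units of w) for snapping values sitting just below a bin boundary
BOUNDARY_GUARD = 1e-9


@dataclass(eq=False)
class AggregatedDataset:
    """Probe × time-point matrix (log2 units) after replicate aggregation."""

    probe_ids: list[str]
    timepoint_order: list[str]
    values: np.ndarray
    method: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.timepoint_order)):
            raise ValidationError(
                f"aggregated matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.timepoint_order)} time points"
            )

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoint_order)

    def row(self, probe: str) -> np.ndarray:
        try:
            return self.values[self.probe_ids.index(probe)]
        except ValueError:
            raise KeyError(f"unknown probe '{probe}'") from None

    def fingerprint(self) -> str:
        """Content hash used to tie derived artifacts back to their source."""
        h = hashlib.sha256()
        h.update("\x1f".join(self.probe_ids).encode())
        h.update("\x1f".join(self.timepoint_order).encode())
        h.update(np.ascontiguousarray(self.values).tobytes())
        return h.hexdigest()[:16]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AggregatedDataset):
            return NotImplemented
        return (
            self.probe_ids == other.probe_ids
            and self.timepoint_order == other.timepoint_order
            and self.method == other.method
            and self.provenance == other.provenance
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclass(eq=False)
class DiscretizedTrajectorySet:
    """Integer bin sequences, one per retained probe, at equi-width ``bin_width``."""

    probe_ids: list[str]
    bin_width: float
    trajectories: np.ndarray
    excluded_probes: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValidationError("bin_width must be > 0")
        self.trajectories = np.asarray(self.trajectories, dtype=int)
        if self.trajectories.ndim != 2 or self.trajectories.shape[0] != len(self.probe_ids):
            raise ValidationError("trajectory matrix must be probes x time points")

    @property
    def n_timepoints(self) -> int:
        return self.trajectories.shape[1]

    def trajectory(self, probe: str) -> tuple[int, ...]:
        try:
            idx = self.probe_ids.index(probe)
        except ValueError:
            raise KeyError(f"unknown probe '{probe}'") from None
        return tuple(int(b) for b in self.trajectories[idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DiscretizedTrajectorySet):
            return NotImplemented
        return (
            self.probe_ids == other.probe_ids
            and self.bin_width == other.bin_width
            and self.excluded_probes == other.excluded_probes
            and self.provenance == other.provenance
            and np.array_equal(self.trajectories, other.trajectories)
        )


def aggregate_replicates(
    ds: ExpressionDataset, method: str = "median"
) -> tuple[AggregatedDataset, LoadReport]:
    """Collapse replicate samples at each time point to their mean or median.

    A cell stays missing only when every replicate at that (probe, time
    point) was missing; such cells are counted in the report.
    """
    if method not in ("mean", "median"):
        raise ValueError(f"method must be 'mean' or 'median', got '{method}'")
    reducer = np.nanmean if method == "mean" else np.nanmedian
    report = LoadReport()
    columns = []
    for tp in ds.timepoint_order:
        idx = [ds.sample_ids.index(s) for s in ds.samples_at(tp)]
        block = ds.values[:, idx]
        with np.errstate(invalid="ignore"):
            all_missing = np.isnan(block).all(axis=1)
            col = np.where(all_missing, np.nan, reducer(np.where(all_missing[:, None], 0.0, block), axis=1))
        report.n_missing_cells += int(all_missing.sum())
        columns.append(col)
    values = np.column_stack(columns)
    agg = AggregatedDataset(
        probe_ids=list(ds.probe_ids),
        timepoint_order=list(ds.timepoint_order),
        values=values,
        method=method,
        provenance={"operation": "aggregate_replicates", "method": method},
    )
    report.n_probes = len(agg.probe_ids)
    report.n_timepoints = agg.n_timepoints
    return agg, report


def segment_aggregate(
    agg: AggregatedDataset, segment_length: int, method: str = "median"
) -> tuple[AggregatedDataset, LoadReport]:
    """Cut the time axis into consecutive segments and aggregate each.

    The final segment may be partial; it is kept, aggregated over its
    members, and flagged in the report.  New time-point labels record the
    member range, e.g. ``"t1..t2"``.
    """
    if method not in ("mean", "median"):
        raise ValueError(f"method must be 'mean' or 'median', got '{method}'")
    if segment_length < 1:
        raise ValueError("segment_length must be >= 1")
    n = agg.n_timepoints
    if segment_length > n:
        raise ValueError(f"segment_length {segment_length} exceeds {n} time points")
    reducer = np.nanmean if method == "mean" else np.nanmedian
    report = LoadReport()
    if segment_length == 1:
        out = AggregatedDataset(
            probe_ids=list(agg.probe_ids),
            timepoint_order=list(agg.timepoint_order),
            values=agg.values.copy(),
            method=agg.method,
            provenance={**agg.provenance, "segment_length": 1},
        )
        report.n_timepoints = n
        return out, report

    columns, labels = [], []
    for start in range(0, n, segment_length):
        stop = min(start + segment_length, n)
        block = agg.values[:, start:stop]
        with np.errstate(invalid="ignore"):
            all_missing = np.isnan(block).all(axis=1)
            col = np.where(
                all_missing, np.nan, reducer(np.where(all_missing[:, None], 0.0, block), axis=1)
            )
        columns.append(col)
        members = agg.timepoint_order[start:stop]
        labels.append(members[0] if len(members) == 1 else f"{members[0]}..{members[-1]}")
        if stop - start < segment_length:
            report.warn(
                f"final segment '{labels[-1]}' is partial ({stop - start} of "
                f"{segment_length} time points)"
            )
    out = AggregatedDataset(
        probe_ids=list(agg.probe_ids),
        timepoint_order=labels,
        values=np.column_stack(columns),
        method=method,
        provenance={
            **agg.provenance,
            "operation": "segment_aggregate",
            "segment_length": segment_length,
        },
    )
    report.n_timepoints = len(labels)
    return out, report


def bin_index(values: np.ndarray | float, w: float) -> np.ndarray | int:
    """Equi-width bin: ``floor(e/w)`` with the boundary guard applied."""
    if w <= 0:
        raise ValueError("bin width must be > 0")
    scaled = np.asarray(values, dtype=float) / w
    bins = np.floor(scaled + BOUNDARY_GUARD)
    if bins.ndim == 0:
        return int(bins)
    return bins.astype(int)


def discretize(
    agg: AggregatedDataset, w: float
) -> tuple[DiscretizedTrajectorySet, LoadReport]:
    """Discretize every full-length profile into integer bin sequences.

    Probes with any missing aggregated cell are excluded (trajectory
    operators need full-length sequences) and listed in the report.
    """
    if w <= 0:
        raise ValueError("bin width must be > 0")
    report = LoadReport()
    complete = ~np.isnan(agg.values).any(axis=1)
    excluded = [p for p, ok in zip(agg.probe_ids, complete) if not ok]
    if excluded:
        report.warn(f"{len(excluded)} probes excluded due to missing aggregated values")
    kept = [p for p, ok in zip(agg.probe_ids, complete) if ok]
    trajectories = bin_index(agg.values[complete], w)
    dset = DiscretizedTrajectorySet(
        probe_ids=kept,
        bin_width=w,
        trajectories=trajectories.reshape(len(kept), agg.n_timepoints),
        excluded_probes=excluded,
        provenance={"source": agg.fingerprint(), "width": w},
    )
    report.n_probes = len(kept)
    report.n_timepoints = agg.n_timepoints
    return dset, report


def undiscretize_view(
    dset: DiscretizedTrajectorySet, agg: AggregatedDataset
) -> dict[str, tuple[np.ndarray, tuple[int, ...]]]:
    """Pair each retained probe's raw profile with its bin sequence.

    Supports hybrid-view exports that switch between discretized and
    non-discretized trajectories.  Raises if ``dset`` was not derived from
    ``agg``.
    """
    if dset.provenance.get("source") != agg.fingerprint():
        raise ValidationError(
            "discretized set was not derived from this aggregated dataset"
        )
    index = {p: i for i, p in enumerate(agg.probe_ids)}
    return {
        probe: (agg.values[index[probe]].copy(), tuple(int(b) for b in dset.trajectories[i]))
        for i, probe in enumerate(dset.probe_ids)
    }
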