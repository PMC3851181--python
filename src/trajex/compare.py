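"""Cross-dataset comparison: primary/secondary pairing and differencing.

Time points are matched by position (first with first, ...), not by label;
a warning is recorded when the labels differ, since control and treatment
arms often name the same design positions differently.  Differencing
operates on aggregated datasets, after replicate aggregation, because
replicate counts may differ between arms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import LoadReport
from .preprocess import AggregatedDataset


@dataclass
class ComparisonPair:
    """A primary and secondary dataset aligned on shared probes and positions."""

    primary: AggregatedDataset
    secondary: AggregatedDataset
    shared_probes: list[str]
    shared_timepoints: list[str]


@dataclass(eq=False)
class SubtractiveProfile:
    """One probe's primary, secondary, and difference profiles."""

    probe: str
    timepoint_order: list[str]
    primary: np.ndarray
    secondary: np.ndarray
    difference: np.ndarray

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SubtractiveProfile):
            return NotImplemented
        return (
            self.probe == other.probe
            and self.timepoint_order == other.timepoint_order
            and np.array_equal(self.primary, other.primary, equal_nan=True)
            and np.array_equal(self.secondary, other.secondary, equal_nan=True)
            and np.array_equal(self.difference, other.difference, equal_nan=True)
        )


def make_pair(
    primary: AggregatedDataset, secondary: AggregatedDataset
) -> tuple[ComparisonPair, LoadReport]:
    """Align two aggregated datasets on their shared probes.

    Requires equal time-point counts and at least one shared probe; probes
    dropped on either side are listed in the report.
    """
    report = LoadReport()
    if primary.n_timepoints != secondary.n_timepoints:
        raise ValueError(
            f"time-point counts differ: {primary.n_timepoints} vs "
            f"{secondary.n_timepoints}"
        )
    secondary_set = set(secondary.probe_ids)
    shared = [p for p in primary.probe_ids if p in secondary_set]
    if not shared:
        raise ValueError("datasets share no probes")
    dropped_primary = [p for p in primary.probe_ids if p not in secondary_set]
    primary_set = set(primary.probe_ids)
    dropped_secondary = [p for p in secondary.probe_ids if p not in primary_set]
    if dropped_primary:
        report.unmatched["primary_only"] = dropped_primary
    if dropped_secondary:
        report.unmatched["secondary_only"] = dropped_secondary
    if primary.timepoint_order != secondary.timepoint_order:
        report.warn(
            "time-point labels differ between arms; matching by position"
        )
    report.n_probes = len(shared)
    report.n_timepoints = primary.n_timepoints
    return (
        ComparisonPair(
            primary=primary,
            secondary=secondary,
            shared_probes=shared,
            shared_timepoints=list(primary.timepoint_order),
        ),
        report,
    )


def _aligned_values(pair: ComparisonPair) -> tuple[np.ndarray, np.ndarray]:
    pi = {p: i for i, p in enumerate(pair.primary.probe_ids)}
    si = {p: i for i, p in enumerate(pair.secondary.probe_ids)}
    rows_p = [pi[p] for p in pair.shared_probes]
    rows_s = [si[p] for p in pair.shared_probes]
    return pair.primary.values[rows_p], pair.secondary.values[rows_s]


def differential_dataset(pair: ComparisonPair) -> AggregatedDataset:
    """Per-probe, per-position difference: primary minus secondary.

    The result is a regular aggregated dataset and feeds discretization,
    clustering and filtering unchanged.
    """
    vp, vs = _aligned_values(pair)
    return AggregatedDataset(
        probe_ids=list(pair.shared_probes),
        timepoint_order=list(pair.shared_timepoints),
        values=vp - vs,
        method=pair.primary.method,
        provenance={
            "operation": "differential",
            "primary": pair.primary.fingerprint(),
            "secondary": pair.secondary.fingerprint(),
        },
    )


def subtractive_profile(pair: ComparisonPair, probe: str) -> SubtractiveProfile:
    """Primary, secondary and difference profiles for one shared probe."""
    if probe not in pair.shared_probes:
        raise KeyError(f"probe '{probe}' is not shared between the datasets")
    vp, vs = _aligned_values(pair)
    idx = pair.shared_probes.index(probe)
    return SubtractiveProfile(
        probe=probe,
        timepoint_order=list(pair.shared_timepoints),
        primary=vp[idx].copy(),
        secondary=vs[idx].copy(),
        difference=vp[idx] - vs[idx],
    )
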