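import numpy as np
import pytest

from trajex.dataio import ExpressionDataset
from trajex.preprocess import AggregatedDataset, DiscretizedTrajectorySet


def make_dataset(values, n_timepoints, reps_per_tp=2, probe_ids=None):
    """Small helper: probe x sample matrix with reps_per_tp samples per time point."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    assert n_samples == n_timepoints * reps_per_tp
    probes = probe_ids or [f"P{i + 1}" for i in range(n_probes)]
    samples, mapping = [], {}
    for t in range(n_timepoints):
        for r in range(reps_per_tp):
            sid = f"s_t{t + 1}_r{r + 1}"
            samples.append(sid)
            mapping[sid] = f"t{t + 1}"
    return ExpressionDataset(
        probe_ids=probes,
        sample_ids=samples,
        values=values,
        sample_to_timepoint=mapping,
        timepoint_order=[f"t{t + 1}" for t in range(n_timepoints)],
    )


def make_agg(values, probe_ids=None, method="median"):
    values = np.asarray(values, dtype=float)
    probes = probe_ids or [f"P{i + 1}" for i in range(values.shape[0])]
    return AggregatedDataset(
        probe_ids=probes,
        timepoint_order=[f"t{t + 1}" for t in range(values.shape[1])],
        values=values,
        method=method,
    )


def make_dset(trajectories, w=0.5, probe_ids=None):
    trajectories = np.asarray(trajectories, dtype=int)
    probes = probe_ids or [f"P{i + 1}" for i in range(trajectories.shape[0])]
    return DiscretizedTrajectorySet(
        probe_ids=probes, bin_width=w, trajectories=trajectories
    )


@pytest.fixture
def toy_dataset():
    # 3 probes x 4 samples, 2 time points x 2 replicates
    return make_dataset(
        [[1.0, 2.0, 3.0, 4.0], [0.0, 0.0, 1.0, 1.0], [5.0, 6.0, 5.0, 6.0]],
        n_timepoints=2,
        reps_per_tp=2,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
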