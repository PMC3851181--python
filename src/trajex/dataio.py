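"""Readers/writers for the external formats and the JSON result store.

External interfaces
-------------------
* expression matrix: TSV, header row of sample IDs, first column probe IDs,
  ``#``-prefixed comment lines ignored; cells are numeric or a missing token
* sample map: TSV with columns ``sample_id``, ``timepoint`` and an optional
  integer ``order`` column fixing the time-point order
* gene sets: GMT (name TAB description TAB member ...)
* probe annotations / labels: two-column TSV (probe, value)
* results: JSON documents carrying a ``schema_version`` field
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np

SCHEMA_VERSION = 1

#: cell tokens treated as missing values; anything else non-numeric is an error
MISSING_TOKENS = frozenset({"NA", "NaN", ""})


class DataFormatError(ValueError):
    """Raised when an input file violates the declared dialect."""


class ValidationError(ValueError):
    """Raised when parsed data violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class LoadReport:
    """Bookkeeping produced by the loaders, never silently discarded."""

    n_probes: int = 0
    n_samples: int = 0
    n_timepoints: int = 0
    n_missing_cells: int = 0
    warnings: list[str] = field(default_factory=list)
    unmatched: dict[str, list[str]] = field(default_factory=dict)

    def warn(self, message: str) -> None:
        self.warnings.append(message)


@dataclass(eq=False)
class ExpressionDataset:
    """Probe × sample matrix of log2 expression with replicate structure.

    ``values`` has one row per probe and one column per sample; missing
    cells are ``NaN``.  Every sample maps to exactly one time-point label and
    every label in ``timepoint_order`` owns at least one sample.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    sample_to_timepoint: dict[str, str]
    timepoint_order: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("duplicate probe IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample IDs")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        unknown = [s for s in self.sample_ids if s not in self.sample_to_timepoint]
        if unknown:
            raise ValidationError(
                "samples missing from the sample map: " + ", ".join(unknown)
            )
        bad_tp = sorted(
            {
                tp
                for s, tp in self.sample_to_timepoint.items()
                if s in self.sample_ids and tp not in self.timepoint_order
            }
        )
        if bad_tp:
            raise ValidationError(
                "time points absent from timepoint_order: " + ", ".join(bad_tp)
            )
        occupied = {self.sample_to_timepoint[s] for s in self.sample_ids}
        empty = [tp for tp in self.timepoint_order if tp not in occupied]
        if empty:
            raise ValidationError("time points with no samples: " + ", ".join(empty))

    def samples_at(self, timepoint: str) -> list[str]:
        return [s for s in self.sample_ids if self.sample_to_timepoint[s] == timepoint]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        return (
            self.probe_ids == other.probe_ids
            and self.sample_ids == other.sample_ids
            and self.sample_to_timepoint == other.sample_to_timepoint
            and self.timepoint_order == other.timepoint_order
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclass
class AnnotationSet:
    """Probe→gene map plus named probe sets (pathways and user labels)."""

    probe_to_gene: dict[str, str] = field(default_factory=dict)
    pathways: dict[str, frozenset[str]] = field(default_factory=dict)
    labels: dict[str, frozenset[str]] = field(default_factory=dict)

    def named_sets(self) -> dict[str, frozenset[str]]:
        """All named sets; labels shadow pathways on name collision."""
        merged: dict[str, frozenset[str]] = dict(self.pathways)
        merged.update(self.labels)
        return merged


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _data_rows(path: str | Path) -> Iterable[list[str]]:
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or (row[0].startswith("#")):
                continue
            yield row


def read_sample_map(path: str | Path, report: LoadReport | None = None) -> tuple[dict[str, str], list[str]]:
    """Parse the sample map TSV into (sample→timepoint, ordered timepoints)."""
    report = report if report is not None else LoadReport()
    rows = list(_data_rows(path))
    if not rows:
        raise DataFormatError(f"{path}: empty sample map")
    header = [h.strip() for h in rows[0]]
    if "sample_id" not in header or "timepoint" not in header:
        raise DataFormatError(
            f"{path}: sample map needs 'sample_id' and 'timepoint' columns, got {header}"
        )
    i_s, i_t = header.index("sample_id"), header.index("timepoint")
    i_o = header.index("order") if "order" in header else None
    mapping: dict[str, str] = {}
    order_of: dict[str, int] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) <= max(i_s, i_t):
            raise DataFormatError(f"{path}:{lineno}: short row")
        sample, tp = row[i_s].strip(), row[i_t].strip()
        if sample in mapping:
            raise DataFormatError(f"{path}:{lineno}: duplicate sample '{sample}'")
        mapping[sample] = tp
        if i_o is not None and len(row) > i_o and row[i_o].strip():
            try:
                rank = int(row[i_o])
            except ValueError as exc:
                raise DataFormatError(
                    f"{path}:{lineno}: non-integer order '{row[i_o]}'"
                ) from exc
            if tp in order_of and order_of[tp] != rank:
                raise DataFormatError(
                    f"{path}:{lineno}: conflicting order for time point '{tp}'"
                )
            order_of[tp] = rank
    timepoints = set(mapping.values())
    if order_of:
        missing = timepoints - set(order_of)
        if missing:
            raise DataFormatError(
                f"{path}: order column present but missing for: {sorted(missing)}"
            )
        ordered = sorted(timepoints, key=lambda tp: order_of[tp])
    else:
        ordered = sorted(timepoints)
        report.warn(
            "sample map has no 'order' column; time points sorted lexically"
        )
    return mapping, ordered


def read_expression_matrix(
    path: str | Path,
    sample_map_path: str | Path,
    *,
    log2: bool = False,
) -> tuple[ExpressionDataset, LoadReport]:
    """Load a probe × sample TSV plus its sample map into a validated dataset.

    ``log2=True`` applies ``log2(x)`` at load for raw-scale inputs; values
    ``<= 0`` are then a hard error.  By default values are assumed to be
    log2-transformed already.
    """
    report = LoadReport()
    mapping, timepoint_order = read_sample_map(sample_map_path, report)

    rows = list(_data_rows(path))
    if not rows:
        raise DataFormatError(f"{path}: empty matrix file")
    sample_ids = [c.strip() for c in rows[0][1:]]
    dup = _first_duplicate(sample_ids)
    if dup is not None:
        raise DataFormatError(f"{path}: duplicate sample ID '{dup}'")
    unmapped = [s for s in sample_ids if s not in mapping]
    if unmapped:
        raise DataFormatError(
            f"{path}: samples absent from the sample map: {', '.join(unmapped)}"
        )

    probe_ids: list[str] = []
    data = np.empty((len(rows) - 1, len(sample_ids)), dtype=float)
    seen: set[str] = set()
    for i, row in enumerate(rows[1:]):
        probe = row[0].strip()
        if probe in seen:
            raise DataFormatError(f"{path}: duplicate probe ID '{probe}'")
        seen.add(probe)
        probe_ids.append(probe)
        if len(row) - 1 != len(sample_ids):
            raise DataFormatError(
                f"{path}: probe '{probe}' has {len(row) - 1} cells, "
                f"expected {len(sample_ids)}"
            )
        for j, cell in enumerate(row[1:]):
            token = cell.strip()
            if token in MISSING_TOKENS:
                data[i, j] = np.nan
                report.n_missing_cells += 1
                continue
            try:
                value = float(token)
            except ValueError as exc:
                raise DataFormatError(
                    f"{path}: non-numeric cell '{token}' at "
                    f"(probe {probe}, sample {sample_ids[j]})"
                ) from exc
            if math.isnan(value):
                report.n_missing_cells += 1
            data[i, j] = value

    if log2:
        with np.errstate(invalid="ignore", divide="ignore"):
            nonpos = (data <= 0) & ~np.isnan(data)
            if nonpos.any():
                i, j = map(int, np.argwhere(nonpos)[0])
                raise ValidationError(
                    f"--log2 requested but value {data[i, j]} <= 0 at "
                    f"(probe {probe_ids[i]}, sample {sample_ids[j]})"
                )
            data = np.log2(data)

    used = {mapping[s] for s in sample_ids}
    order = [tp for tp in timepoint_order if tp in used]
    ds = ExpressionDataset(
        probe_ids=probe_ids,
        sample_ids=sample_ids,
        values=data,
        sample_to_timepoint={s: mapping[s] for s in sample_ids},
        timepoint_order=order,
    )
    report.n_probes = len(ds.probe_ids)
    report.n_samples = len(ds.sample_ids)
    report.n_timepoints = len(ds.timepoint_order)
    return ds, report


def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            return item
        seen.add(item)
    return None


def read_probe_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV (probe, value) → dict; later rows override earlier."""
    table: dict[str, str] = {}
    for lineno, row in enumerate(_data_rows(path), start=1):
        if len(row) < 2:
            raise DataFormatError(f"{path}:{lineno}: expected two columns")
        table[row[0].strip()] = row[1].strip()
    return table


def read_label_table(path: str | Path) -> dict[str, frozenset[str]]:
    """Two-column TSV (probe, label) → label → probe set."""
    groups: dict[str, set[str]] = {}
    for lineno, row in enumerate(_data_rows(path), start=1):
        if len(row) < 2:
            raise DataFormatError(f"{path}:{lineno}: expected two columns")
        groups.setdefault(row[1].strip(), set()).add(row[0].strip())
    return {name: frozenset(members) for name, members in groups.items()}


def read_gene_sets_gmt(
    path: str | Path,
    universe: Iterable[str],
    probe_to_gene: Mapping[str, str] | None = None,
) -> tuple[dict[str, frozenset[str]], LoadReport]:
    """Parse a GMT file into pathway → probe set, restricted to ``universe``.

    Members may be probe IDs or gene symbols; gene symbols are expanded to
    every probe mapping to that gene (many-to-many).  Unmatched members are
    counted in the report, and sets that end up empty are kept with a warning
    so that downstream D=0 handling sees them.
    """
    universe = set(universe)
    gene_to_probes: dict[str, set[str]] = {}
    if probe_to_gene:
        for probe, gene in probe_to_gene.items():
            gene_to_probes.setdefault(gene, set()).add(probe)

    report = LoadReport()
    pathways: dict[str, frozenset[str]] = {}
    for lineno, row in enumerate(_data_rows(path), start=1):
        if len(row) < 2:
            raise DataFormatError(f"{path}:{lineno}: GMT rows need name and description")
        name = row[0].strip()
        if name in pathways:
            raise DataFormatError(f"{path}:{lineno}: duplicate gene set '{name}'")
        members: set[str] = set()
        unmatched: list[str] = []
        for token in (t.strip() for t in row[2:] if t.strip()):
            if token in universe:
                members.add(token)
            elif token in gene_to_probes:
                hit = gene_to_probes[token] & universe
                if hit:
                    members |= hit
                else:
                    unmatched.append(token)
            else:
                unmatched.append(token)
        pathways[name] = frozenset(members)
        if unmatched:
            report.unmatched[name] = sorted(set(unmatched))
        if not members:
            report.warn(f"gene set '{name}' is empty after mapping to the universe")
    return pathways, report


# ---------------------------------------------------------------------------
# JSON result store
# ---------------------------------------------------------------------------


def _matrix_to_json(values: np.ndarray) -> list[list[float | None]]:
    return [
        [None if math.isnan(v) else v for v in row] for row in np.asarray(values, float)
    ]


def _matrix_from_json(rows: list[list[float | None]]) -> np.ndarray:
    return np.array(
        [[np.nan if v is None else float(v) for v in row] for row in rows], dtype=float
    )


def _encode(obj: Any) -> tuple[str, dict[str, Any]]:
    # local imports keep dataio import-light and break the module cycle
    from . import cluster, compare, preprocess, stats, trajectory

    if isinstance(obj, (set, frozenset)):
        return "probe_set", {"probes": sorted(obj)}
    if isinstance(obj, ExpressionDataset):
        return "expression_dataset", {
            "probe_ids": obj.probe_ids,
            "sample_ids": obj.sample_ids,
            "values": _matrix_to_json(obj.values),
            "sample_to_timepoint": obj.sample_to_timepoint,
            "timepoint_order": obj.timepoint_order,
        }
    if isinstance(obj, AnnotationSet):
        return "annotation_set", {
            "probe_to_gene": obj.probe_to_gene,
            "pathways": {k: sorted(v) for k, v in obj.pathways.items()},
            "labels": {k: sorted(v) for k, v in obj.labels.items()},
        }
    if isinstance(obj, preprocess.AggregatedDataset):
        return "aggregated_dataset", {
            "probe_ids": obj.probe_ids,
            "timepoint_order": obj.timepoint_order,
            "values": _matrix_to_json(obj.values),
            "method": obj.method,
            "provenance": obj.provenance,
        }
    if isinstance(obj, preprocess.DiscretizedTrajectorySet):
        return "discretized_trajectory_set", {
            "probe_ids": obj.probe_ids,
            "bin_width": obj.bin_width,
            "trajectories": np.asarray(obj.trajectories, int).tolist(),
            "excluded_probes": obj.excluded_probes,
            "provenance": obj.provenance,
        }
    if isinstance(obj, trajectory.TrajectoryGraph):
        nodes = trajectory.ordered_nodes(obj)
        return "trajectory_graph", {
            "n_timepoints": obj.n_timepoints,
            "nodes": [
                {"prefix": list(prefix), "members": sorted(obj.node_members[prefix])}
                for prefix in nodes
            ],
            "edges": [
                [list(parent), list(child)] for parent, child in obj.sorted_edges()
            ],
        }
    if isinstance(obj, cluster.Partition):
        return "partition", {
            "method": obj.method,
            "params": obj.params,
            "groups": [
                {"key": list(k) if isinstance(k, tuple) else k, "members": sorted(v)}
                for k, v in obj.sorted_groups()
            ],
        }
    if isinstance(obj, compare.SubtractiveProfile):
        return "subtractive_profile", {
            "probe": obj.probe,
            "timepoint_order": obj.timepoint_order,
            "primary": _matrix_to_json([obj.primary])[0],
            "secondary": _matrix_to_json([obj.secondary])[0],
            "difference": _matrix_to_json([obj.difference])[0],
        }
    if isinstance(obj, list) and all(isinstance(r, stats.EnrichmentResult) for r in obj):
        return "enrichment_table", {
            "rows": [
                {
                    "set_name": r.set_name,
                    "N": r.N,
                    "D": r.D,
                    "n": r.n,
                    "k": r.k,
                    "p_point": r.p_point,
                    "p_tail": r.p_tail,
                    "q": r.q,
                }
                for r in obj
            ]
        }
    if isinstance(obj, list) and all(isinstance(r, stats.TrajectoryStat) for r in obj):
        return "trajectory_stats", {
            "rows": [
                {"probe": r.probe, "volatility": r.volatility, "linear_trend": r.linear_trend}
                for r in obj
            ],
            "units": obj[0].units if obj else "log2",
        }
    raise TypeError(f"cannot serialize result of type {type(obj).__name__}")


def _decode(kind: str, data: dict[str, Any]) -> Any:
    from . import cluster, compare, preprocess, stats, trajectory

    if kind == "probe_set":
        return set(data["probes"])
    if kind == "expression_dataset":
        return ExpressionDataset(
            probe_ids=list(data["probe_ids"]),
            sample_ids=list(data["sample_ids"]),
            values=_matrix_from_json(data["values"]),
            sample_to_timepoint=dict(data["sample_to_timepoint"]),
            timepoint_order=list(data["timepoint_order"]),
        )
    if kind == "annotation_set":
        return AnnotationSet(
            probe_to_gene=dict(data["probe_to_gene"]),
            pathways={k: frozenset(v) for k, v in data["pathways"].items()},
            labels={k: frozenset(v) for k, v in data["labels"].items()},
        )
    if kind == "aggregated_dataset":
        return preprocess.AggregatedDataset(
            probe_ids=list(data["probe_ids"]),
            timepoint_order=list(data["timepoint_order"]),
            values=_matrix_from_json(data["values"]),
            method=data["method"],
            provenance=dict(data["provenance"]),
        )
    if kind == "discretized_trajectory_set":
        return preprocess.DiscretizedTrajectorySet(
            probe_ids=list(data["probe_ids"]),
            bin_width=float(data["bin_width"]),
            trajectories=np.asarray(data["trajectories"], dtype=int),
            excluded_probes=list(data["excluded_probes"]),
            provenance=dict(data["provenance"]),
        )
    if kind == "trajectory_graph":
        members = {
            tuple(node["prefix"]): frozenset(node["members"]) for node in data["nodes"]
        }
        return trajectory.TrajectoryGraph.from_node_members(
            members, n_timepoints=int(data["n_timepoints"])
        )
    if kind == "partition":
        groups = {
            tuple(g["key"]) if isinstance(g["key"], list) else g["key"]: frozenset(
                g["members"]
            )
            for g in data["groups"]
        }
        return cluster.Partition(groups=groups, method=data["method"], params=data["params"])
    if kind == "subtractive_profile":
        return compare.SubtractiveProfile(
            probe=data["probe"],
            timepoint_order=list(data["timepoint_order"]),
            primary=_matrix_from_json([data["primary"]])[0],
            secondary=_matrix_from_json([data["secondary"]])[0],
            difference=_matrix_from_json([data["difference"]])[0],
        )
    if kind == "enrichment_table":
        return [stats.EnrichmentResult(**row) for row in data["rows"]]
    if kind == "trajectory_stats":
        units = data.get("units", "log2")
        return [stats.TrajectoryStat(units=units, **row) for row in data["rows"]]
    raise TypeError(f"unknown result type '{kind}'")


def write_matrix_tsv(
    probe_ids: list[str],
    column_ids: list[str],
    values: np.ndarray,
    path: str | Path,
    precision: int = 6,
) -> None:
    """Write a probe × column matrix in the expression-matrix TSV dialect.

    Fixed decimal precision keeps outputs byte-stable across platforms.
    """
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        fh.write("probe\t" + "\t".join(column_ids) + "\n")
        for probe, row in zip(probe_ids, values):
            cells = ["NA" if math.isnan(v) else f"{v:.{precision}f}" for v in row]
            fh.write(probe + "\t" + "\t".join(cells) + "\n")


def write_sample_map_tsv(
    sample_to_timepoint: Mapping[str, str],
    timepoint_order: list[str],
    path: str | Path,
) -> None:
    """Write a sample map TSV with an explicit order column."""
    rank = {tp: i + 1 for i, tp in enumerate(timepoint_order)}
    with open(path, "w") as fh:
        fh.write("sample_id\ttimepoint\torder\n")
        for sample, tp in sample_to_timepoint.items():
            fh.write(f"{sample}\t{tp}\t{rank[tp]}\n")


def write_result(obj: Any, path: str | Path) -> None:
    """Serialize a result object to a versioned JSON document."""
    kind, data = _encode(obj)
    doc = {"schema_version": SCHEMA_VERSION, "type": kind, "data": data}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_result(path: str | Path) -> Any:
    """Inverse of :func:`write_result`."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise DataFormatError(
            f"{path}: unsupported schema_version {doc.get('schema_version')!r}"
        )
    return _decode(doc["type"], doc["data"])
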