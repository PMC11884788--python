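"""Trajectory data model and CSV I/O.

Single-cell translocation responses are stored as cells x timepoints
matrices on a common minute grid, with stimulation at minute 0 and a few
pre-stimulation frames at negative minutes.  A cause-candidate channel
(e.g. SOS) and a result-candidate channel (e.g. RAF) measured
simultaneously in the same cells form a :class:`PairedDataset`.

CSV schema: first column ``cell_id``; remaining columns are named by the
integer (or decimal) minute relative to stimulation, e.g.
``cell_id,-3,-2,-1,0,1,...``.  One file per channel per condition;
condition metadata lives in a sidecar manifest, not in filenames.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TimeGrid",
    "TraceMatrix",
    "ConditionMeta",
    "PairedDataset",
    "read_trace_csv",
    "write_trace_csv",
    "pair_channels",
    "concat_datasets",
    "load_manifest",
]


def _fmt_minute(m: float) -> str:
    return str(int(m)) if float(m).is_integer() else repr(float(m))


@dataclass(frozen=True)
class TimeGrid:
    """Uniform minute grid with stimulation at minute 0.

    Parameters
    ----------
    times
        Strictly increasing, uniformly spaced times in minutes relative
        to stimulation (negative = pre-stimulation).
    """

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("TimeGrid needs at least two time points")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("times must be uniformly spaced")
        t.setflags(write=False)
        object.__setattr__(self, "times", t)

    @classmethod
    def regular(cls, start: float = -3, stop: float = 60, dt: float = 1.0) -> "TimeGrid":
        n = int(round((stop - start) / dt)) + 1
        return cls(start + dt * np.arange(n))

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_pre(self) -> int:
        """Number of pre-stimulation frames (times < 0)."""
        return int(np.sum(self.times < 0))

    def index_of(self, minute: float) -> int:
        idx = np.nonzero(np.isclose(self.times, minute, rtol=0, atol=1e-6))[0]
        if idx.size == 0:
            raise KeyError(f"time {minute} min is not on the grid")
        return int(idx[0])

    def __len__(self) -> int:
        return self.times.size

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TimeGrid) and np.array_equal(self.times, other.times)

    def __hash__(self) -> int:
        return hash(self.times.tobytes())


@dataclass(frozen=True)
class TraceMatrix:
    """Cells x timepoints response values for one channel."""

    values: np.ndarray
    grid: TimeGrid
    channel: str
    cell_ids: tuple

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (cells x timepoints)")
        ids = tuple(str(c) for c in self.cell_ids)
        if v.shape[0] != len(ids):
            raise ValueError(
                f"{v.shape[0]} rows but {len(ids)} cell ids"
            )
        if v.shape[1] != len(self.grid):
            raise ValueError(
                f"{v.shape[1]} columns but grid has {len(self.grid)} times"
            )
        if v.size and not np.all(np.isfinite(v)):
            raise ValueError("non-finite values (NaN/inf or ragged input rows)")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "cell_ids", ids)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def column(self, minute: float) -> np.ndarray:
        """Per-cell values at one time point."""
        return self.values[:, self.grid.index_of(minute)]

    def subset(self, index: Sequence[int]) -> "TraceMatrix":
        index = np.asarray(index, dtype=int)
        return TraceMatrix(
            self.values[index],
            self.grid,
            self.channel,
            tuple(self.cell_ids[i] for i in index),
        )


@dataclass(frozen=True)
class ConditionMeta:
    """Experimental condition labels for one dataset.

    ``egf_dose`` in ng/ml (0 = vehicle stimulation); ``inhibitor_nm`` is
    the inhibitor concentration in nM (0 = vehicle pre-treatment).
    """

    egf_dose: float = 0.0
    genotype: str = "wt"
    inhibitor: str = "vehicle"
    inhibitor_nm: float = 0.0
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        if self.egf_dose < 0:
            raise ValueError("egf_dose must be >= 0")
        if self.inhibitor_nm < 0:
            raise ValueError("inhibitor_nm must be >= 0")

    @property
    def label(self) -> str:
        parts = [f"egf={self.egf_dose:g}", self.genotype, self.inhibitor]
        if self.inhibitor != "vehicle":
            parts.append(f"{self.inhibitor_nm:g}nM")
        if self.replicate_id:
            parts.append(str(self.replicate_id))
        return "|".join(parts)


@dataclass(frozen=True)
class PairedDataset:
    """Cell-aligned cause/result trace pair with condition metadata.

    ``provenance`` (optional) labels each cell with the condition it was
    pooled from; ``sources`` maps those labels back to their
    :class:`ConditionMeta`.  Both are populated by
    :func:`concat_datasets` and preserved through subsetting, so a
    pooled dataset can always be split back into its parts.
    """

    cause: TraceMatrix
    result: TraceMatrix
    condition: ConditionMeta | None = None
    provenance: tuple | None = None
    sources: Mapping[str, ConditionMeta | None] | None = None

    def __post_init__(self) -> None:
        if self.cause.cell_ids != self.result.cell_ids:
            raise ValueError("cause and result must share identical cell ids and order")
        if self.cause.grid != self.result.grid:
            raise ValueError("cause and result must share the same time grid")
        if self.provenance is not None and len(self.provenance) != self.n_cells:
            raise ValueError("provenance must have one label per cell")

    @property
    def n_cells(self) -> int:
        return self.cause.n_cells

    @property
    def grid(self) -> TimeGrid:
        return self.cause.grid

    @property
    def cell_ids(self) -> tuple:
        return self.cause.cell_ids

    def subset(self, index: Sequence[int]) -> "PairedDataset":
        index = np.asarray(index, dtype=int)
        prov = (
            tuple(self.provenance[i] for i in index)
            if self.provenance is not None
            else None
        )
        return PairedDataset(
            self.cause.subset(index),
            self.result.subset(index),
            self.condition,
            prov,
            self.sources,
        )

    def split_by_provenance(self) -> dict:
        """Recover the constituent datasets of a pooled dataset."""
        if self.provenance is None:
            raise ValueError("dataset carries no provenance labels")
        out = {}
        prov = np.asarray(self.provenance, dtype=object)
        for label in dict.fromkeys(self.provenance):  # preserve order
            idx = np.nonzero(prov == label)[0]
            part = self.subset(idx)
            cond = self.sources.get(label) if self.sources else None
            out[label] = replace(part, condition=cond, provenance=None, sources=None)
        return out


# ---------------------------------------------------------------------------
# CSV I/O


def read_trace_csv(path: str | os.PathLike, channel: str, grid: TimeGrid | None = None) -> TraceMatrix:
    """Read a trajectory table (``cell_id`` column + one column per minute).

    If ``grid`` is given the file's time columns must match it exactly;
    otherwise the grid is inferred from the header.  Ragged or
    non-numeric rows are rejected.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a cell_id column plus time columns")
    try:
        times = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}: time columns must be numeric minutes") from exc
    file_grid = TimeGrid(times)
    if grid is not None:
        if len(grid) != len(file_grid) or not np.allclose(grid.times, file_grid.times):
            raise ValueError(
                f"{path}: file grid ({len(file_grid)} cols) does not match the "
                f"declared grid ({len(grid)} cols)"
            )
        file_grid = grid
    try:
        values = df.iloc[:, 1:].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell value") from exc
    return TraceMatrix(values, file_grid, channel, tuple(df.iloc[:, 0].astype(str)))


def write_trace_csv(trace: TraceMatrix, path: str | os.PathLike) -> str:
    """Write a TraceMatrix in the schema read by :func:`read_trace_csv`."""
    if trace.values.size and not np.all(np.isfinite(trace.values)):
        raise ValueError("refusing to write non-finite values")
    cols = ["cell_id"] + [_fmt_minute(t) for t in trace.grid.times]
    df = pd.DataFrame(
        np.column_stack([np.array(trace.cell_ids, dtype=object), trace.values.astype(object)])
        if trace.n_cells
        else np.empty((0, len(cols)), dtype=object),
        columns=cols,
    )
    df.to_csv(path, index=False)
    return str(path)


def pair_channels(
    cause: TraceMatrix,
    result: TraceMatrix,
    condition: ConditionMeta | None = None,
    intersect: bool = False,
) -> PairedDataset:
    """Pair simultaneously measured channels cell-by-cell.

    Cells present in only one channel are an error unless
    ``intersect=True``, in which case the common cells (in cause order)
    are kept.  A grid mismatch is always fatal.
    """
    if cause.grid != result.grid:
        raise ValueError("channels measured on different time grids cannot be paired")
    if cause.cell_ids != result.cell_ids:
        common = set(cause.cell_ids) & set(result.cell_ids)
        if not intersect:
            raise ValueError(
                "cell id mismatch between channels "
                f"({len(common)} shared); pass intersect=True to keep the overlap"
            )
        ci = [i for i, c in enumerate(cause.cell_ids) if c in common]
        pos = {c: i for i, c in enumerate(result.cell_ids)}
        ri = [pos[cause.cell_ids[i]] for i in ci]
        cause, result = cause.subset(ci), result.subset(ri)
    return PairedDataset(cause, result, condition)


def concat_datasets(datasets: Sequence[PairedDataset]) -> PairedDataset:
    """Row-stack datasets (e.g. pool EGF doses), keeping per-cell provenance.

    The pooled dataset carries a ``provenance`` label per cell naming
    its source condition, so :meth:`PairedDataset.split_by_provenance`
    recovers the parts exactly.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("nothing to concatenate")
    if len(datasets) == 1:
        return datasets[0]
    grid = datasets[0].grid
    cname = datasets[0].cause.channel
    rname = datasets[0].result.channel
    for d in datasets[1:]:
        if d.grid != grid:
            raise ValueError("all datasets must share the same time grid")
        if d.cause.channel != cname or d.result.channel != rname:
            raise ValueError("channel labels differ between datasets")
    labels, sources, prov = [], {}, []
    for k, d in enumerate(datasets):
        label = d.condition.label if d.condition is not None else f"part{k}"
        if label in sources:
            label = f"{label}#{k}"
        sources[label] = d.condition
        labels.append(label)
        prov.extend([label] * d.n_cells)
    cause = TraceMatrix(
        np.vstack([d.cause.values for d in datasets]),
        grid,
        cname,
        tuple(f"{lab}:{cid}" for lab, d in zip(labels, datasets) for cid in d.cause.cell_ids),
    )
    result = TraceMatrix(np.vstack([d.result.values for d in datasets]), grid, rname, cause.cell_ids)
    return PairedDataset(cause, result, None, tuple(prov), sources)


def load_manifest(path: str | os.PathLike) -> list[PairedDataset]:
    """Load a YAML/JSON dataset manifest into PairedDatasets.

    Manifest format::

        datasets:
          - cause: sos_egf10.csv      # paths relative to the manifest
            result: raf_egf10.csv
            cause_channel: SOS        # optional, default "cause"
            result_channel: RAF
            condition: {egf_dose: 10, genotype: wt, inhibitor: vehicle}
    """
    base = os.path.dirname(os.path.abspath(path))
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    out = []
    for entry in spec["datasets"]:
        cond = ConditionMeta(**entry.get("condition", {}))
        cause = read_trace_csv(
            os.path.join(base, entry["cause"]), entry.get("cause_channel", "cause")
        )
        result = read_trace_csv(
            os.path.join(base, entry["result"]), entry.get("result_channel", "result")
        )
        out.append(pair_channels(cause, result, cond, intersect=bool(entry.get("intersect", False))))
    return out
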