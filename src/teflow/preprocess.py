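"""From per-cell intensity time courses to response traces.

The measurement produces, per cell and per minute, the mean TIR
(membrane-proximal) and epi (whole-cell) fluorescence intensity per
pixel.  The response trace is obtained by: bleed-through subtraction
between the two fluorophore channels, removal of slow drift in the
basal intensity, normalization of the TIR signal to the epi signal, and
subtraction of the 3-frame pre-stimulation baseline of the normalized
signal.  Cells in the bottom 20% of time-0 intensity are removed
(hard to separate from background).

Also here: per-cell response intensities (window sums of the response
trace) and binning of cells by their causal response at Tc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import PairedDataset, TimeGrid, TraceMatrix

__all__ = [
    "IntensityTable",
    "ResponseBinSpec",
    "correct_bleedthrough",
    "remove_drift",
    "normalize_and_baseline",
    "filter_low_intensity",
    "response_intensity",
    "normalize_intensities_to_max",
    "bin_by_causal_response",
]


@dataclass(frozen=True)
class IntensityTable:
    """Raw mean intensities per pixel (a.u.) for one fluorophore channel."""

    tir: np.ndarray
    epi: np.ndarray
    grid: TimeGrid
    cell_ids: tuple
    channel: str = ""

    def __post_init__(self) -> None:
        tir = np.asarray(self.tir, dtype=float)
        epi = np.asarray(self.epi, dtype=float)
        if tir.shape != epi.shape:
            raise ValueError("tir and epi must have the same shape")
        if tir.ndim != 2 or tir.shape[1] != len(self.grid):
            raise ValueError("intensity tables must be cells x grid-times")
        if np.any(tir < 0) or np.any(epi < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "tir", tir)
        object.__setattr__(self, "epi", epi)
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))


@dataclass(frozen=True)
class ResponseBinSpec:
    """Binning of cells by causal response at Tc (equal-width bins).

    ``vmin``/``vmax`` bound the retained response range; if None they
    are set after trimming ``trim_low``/``trim_high`` cells from the
    distribution ends.  Each returned bin must contain at least
    ``min_count`` cells.
    """

    tc: float
    channel: str = "cause"
    bin_size: float = 0.1
    min_count: int = 150
    trim_low: int = 0
    trim_high: int = 0
    vmin: float | None = None
    vmax: float | None = None

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.channel not in ("cause", "result"):
            raise ValueError("channel must be 'cause' or 'result'")


def correct_bleedthrough(
    table_a: IntensityTable,
    table_b: IntensityTable,
    leak_b_into_a: float = 0.0,
    leak_a_into_b: float = 0.0,
    clip: bool = False,
):
    """Subtract linear spectral bleed-through between two fluorophores.

    ``corrected_a = a - leak_b_into_a * b`` (and symmetrically), applied
    to TIR and epi images alike.  Coefficients must lie in [0, 1).
    Negative corrected intensities are kept unless ``clip=True``.
    """
    for c in (leak_b_into_a, leak_a_into_b):
        if not (0 <= c < 1):
            raise ValueError("bleed-through coefficients must be in [0, 1)")

    def _corr(x_a, x_b):
        a = x_a - leak_b_into_a * x_b
        b = x_b - leak_a_into_b * x_a
        if clip:
            a, b = np.clip(a, 0, None), np.clip(b, 0, None)
        return a, b

    tir_a, tir_b = _corr(table_a.tir, table_b.tir)
    epi_a, epi_b = _corr(table_a.epi, table_b.epi)

    def _wrap(tir, epi, src):
        # IntensityTable enforces non-negativity; corrected values that
        # went negative (and were not clipped) come back as a raw pair
        if np.all(tir >= 0) and np.all(epi >= 0):
            return IntensityTable(tir, epi, src.grid, src.cell_ids, src.channel)
        return _RawPair(tir, epi, src)

    return _wrap(tir_a, epi_a, table_a), _wrap(tir_b, epi_b, table_b)


def remove_drift(series: np.ndarray, grid: TimeGrid, method: str = "linear_prestim", reference: np.ndarray | None = None) -> np.ndarray:
    """Remove slow drift in the basal intensity of one cell's series.

    ``linear_prestim``: fit a line to the pre-stimulation frames
    (>= 2 required) and subtract ``slope * t`` so the fitted
    pre-stimulation slope becomes zero (a pure ramp a + b*t becomes the
    constant a).  ``reference_subtract``: subtract a supplied reference
    trend series elementwise.
    """
    series = np.asarray(series, dtype=float)
    if method == "linear_prestim":
        pre = grid.times < 0
        if pre.sum() < 2:
            raise ValueError("linear_prestim needs >= 2 pre-stimulation frames")
        slope = np.polyfit(grid.times[pre], series[pre], 1)[0]
        return series - slope * grid.times
    if method == "reference_subtract":
        if reference is None:
            raise ValueError("reference_subtract needs a reference series")
        reference = np.asarray(reference, dtype=float)
        if reference.shape != series.shape:
            raise ValueError("reference must match the series shape")
        return series - reference
    raise ValueError("method must be 'linear_prestim' or 'reference_subtract'")


def normalize_and_baseline(table: IntensityTable, channel: str | None = None) -> TraceMatrix:
    """TIR/epi ratio minus its 3-frame pre-stimulation average.

    The response at the pre-stimulation frames averages to zero for
    every cell by construction.
    """
    if np.any(table.epi <= 0):
        raise ValueError("epi intensity must be positive at all frames")
    pre_idx = np.nonzero(table.grid.times < 0)[0]
    if pre_idx.size < 3:
        raise ValueError("need >= 3 pre-stimulation frames for the baseline")
    base_idx = pre_idx[-3:]  # the 3 frames immediately before stimulation
    ratio = table.tir / table.epi
    baseline = ratio[:, base_idx].mean(axis=1, keepdims=True)
    return TraceMatrix(ratio - baseline, table.grid, channel or table.channel, table.cell_ids)


def filter_low_intensity(
    dataset: PairedDataset,
    intensity_t0: np.ndarray,
    fraction: float = 0.20,
):
    """Remove the cells with the lowest time-0 signal intensities.

    ``floor(fraction * n)`` cells are removed jointly from both channels
    (the pairing is cell-wise), ranked by ``intensity_t0`` with ties
    broken by stable cell order.  Returns ``(filtered, removed_ids)``.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    intensity = np.asarray(intensity_t0, dtype=float)
    n = dataset.n_cells
    if intensity.shape != (n,):
        raise ValueError("need one intensity per cell")
    k = math.floor(fraction * n)
    order = np.argsort(intensity, kind="stable")  # ties keep cell order
    removed = set(order[:k].tolist())
    keep = [i for i in range(n) if i not in removed]
    if not keep:
        raise ValueError("intensity filter removed every cell")
    removed_ids = tuple(dataset.cell_ids[i] for i in sorted(removed))
    return dataset.subset(keep), removed_ids


def response_intensity(trace: TraceMatrix, window, normalize_by: float | None = None) -> np.ndarray:
    """Per-cell sum of response values over an inclusive minute window.

    ``window=(t_start, t_end)``; the sum runs over every grid column in
    the closed interval.  ``normalize_by`` optionally divides by a
    scalar (e.g. the maximum of condition means, see
    :func:`normalize_intensities_to_max`).
    """
    t_start, t_end = window
    if t_end < t_start:
        raise ValueError("empty window")
    mask = (trace.grid.times >= t_start - 1e-9) & (trace.grid.times <= t_end + 1e-9)
    if not mask.any():
        raise ValueError("window contains no grid times")
    sums = trace.values[:, mask].sum(axis=1)
    if normalize_by is not None:
        if normalize_by == 0:
            raise ValueError("cannot normalize by zero")
        sums = sums / normalize_by
    return sums


def normalize_intensities_to_max(per_condition: dict) -> dict:
    """Normalize per-condition response-intensity arrays to the maximum
    condition mean (the convention of dose-response summaries)."""
    means = {k: float(np.mean(v)) for k, v in per_condition.items()}
    peak = max(means.values())
    if peak == 0:
        raise ValueError("all condition means are zero")
    return {k: np.asarray(v, dtype=float) / peak for k, v in per_condition.items()}


def bin_by_causal_response(dataset: PairedDataset, spec: ResponseBinSpec):
    """Group cells into equal-width bins of the causal response at Tc.

    Returns ``(bins, report)``: ``bins`` is a list of PairedDatasets for
    contiguous bins of width ``bin_size`` covering [vmin, vmax), each
    with at least ``min_count`` cells; ``report`` lists the trimmed-tail
    cell counts and the per-bin counts (never silently dropped).
    """
    trace = dataset.cause if spec.channel == "cause" else dataset.result
    resp = trace.column(spec.tc)
    n = resp.size
    order = np.argsort(resp, kind="stable")
    lo_trim = set(order[: spec.trim_low].tolist()) if spec.trim_low else set()
    hi_trim = set(order[n - spec.trim_high:].tolist()) if spec.trim_high else set()
    kept = np.array([i for i in range(n) if i not in lo_trim and i not in hi_trim])
    if kept.size == 0:
        raise ValueError("trimming removed every cell")
    vmin = spec.vmin if spec.vmin is not None else float(resp[kept].min())
    vmax = spec.vmax if spec.vmax is not None else float(resp[kept].max()) + 1e-12
    if vmax <= vmin:
        raise ValueError("empty response range")
    n_bins = int(math.ceil((vmax - vmin) / spec.bin_size - 1e-9))
    edges = vmin + spec.bin_size * np.arange(n_bins + 1)
    bins, counts, edges_used = [], [], []
    below = int(np.sum(resp[kept] < vmin))
    above = int(np.sum(resp[kept] >= edges[-1]))
    for b in range(n_bins):
        in_bin = kept[(resp[kept] >= edges[b]) & (resp[kept] < edges[b + 1])]
        counts.append(int(in_bin.size))
        edges_used.append((float(edges[b]), float(edges[b + 1])))
        # under-filled bins are reported in the counts, not returned
        bins.append(dataset.subset(in_bin) if in_bin.size >= spec.min_count else None)
    kept_bins = [b for b in bins if b is not None]
    if not kept_bins:
        raise ValueError("no bin reaches min_count cells")
    report = {
        "n_total": n,
        "n_trimmed_low": len(lo_trim),
        "n_trimmed_high": len(hi_trim),
        "n_below_range": below,
        "n_above_range": above,
        "bin_edges": edges_used,
        "bin_counts": counts,
        "n_in_bins": int(sum(c for c, b in zip(counts, bins) if b is not None)),
    }
    return kept_bins, report


class _RawPair:
    """Bleed-through-corrected intensities that went negative somewhere;
    carries the arrays so the caller can inspect or clip explicitly."""

    def __init__(self, tir, epi, src: IntensityTable):
        self.tir = tir
        self.epi = epi
        self.grid = src.grid
        self.cell_ids = src.cell_ids
        self.channel = src.channel
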