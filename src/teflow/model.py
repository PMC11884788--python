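"""Model/Results interface for the TE analysis.

``TransferEntropyModel`` is constructed from a paired dataset plus the
query design (directions, causal times, target range, null/threshold
settings); ``fit`` runs the TE time courses with permutation-null
significance and returns a ``TransferEntropyResults`` carrying the tidy
table, with bootstrap TEsum, summaries, plotting and CSV export
hanging off it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import PairedDataset, read_trace_csv, pair_channels, ConditionMeta
from .gaussian import DIRECTIONS
from .inference import (
    INTERVAL_DEFAULT,
    MIN_CELLS_DEFAULT,
    N_BOOT_DEFAULT,
    N_NULL_DEFAULT,
    PERCENTILE_DEFAULT,
    PeakWindow,
    TEsumEstimate,
    TETimeCourse,
    bootstrap_tesum,
    te_timecourse,
    tesum,
)

__all__ = ["TransferEntropyModel", "TransferEntropyResults"]


class TransferEntropyModel:
    """Transfer-entropy information-flow model for one paired dataset.

    Parameters
    ----------
    dataset
        Cell-aligned cause/result trace pair.
    tc_values
        Causal times Tc (= reference times Tr) in minutes.  Default:
        every integer grid minute from 1 to 35.
    t_max
        Upper end of the target-time range (default: end of record).
    directions
        Subset of ``("fw", "bw")``.
    n_null, percentile
        Permutation-null settings for the significance threshold
        (defaults: 1000 resamples, upper 1% point).
    """

    def __init__(
        self,
        dataset: PairedDataset,
        tc_values: Sequence[float] | None = None,
        t_max: float | None = None,
        directions: Sequence[str] = DIRECTIONS,
        n_null: int = N_NULL_DEFAULT,
        percentile: float = PERCENTILE_DEFAULT,
        min_cells: int = MIN_CELLS_DEFAULT,
        null_method: str = "permutation",
    ) -> None:
        self.dataset = dataset
        grid = dataset.grid
        if tc_values is None:
            tc_values = [t for t in grid.times if 1 <= t <= 35 and float(t).is_integer()]
        self.tc_values = [float(t) for t in tc_values]
        if not self.tc_values:
            raise ValueError("need at least one causal time Tc")
        self.t_max = float(grid.times[-1]) if t_max is None else float(t_max)
        for d in directions:
            if d not in DIRECTIONS:
                raise ValueError(f"unknown direction {d!r}")
        self.directions = tuple(directions)
        self.n_null = int(n_null)
        self.percentile = float(percentile)
        self.min_cells = int(min_cells)
        self.null_method = null_method

    @classmethod
    def from_csv(
        cls,
        cause_path,
        result_path,
        condition: ConditionMeta | None = None,
        cause_channel: str = "cause",
        result_channel: str = "result",
        intersect: bool = False,
        **kwargs,
    ) -> "TransferEntropyModel":
        """Build the model straight from two trajectory CSV files."""
        cause = read_trace_csv(cause_path, cause_channel)
        result = read_trace_csv(result_path, result_channel)
        return cls(pair_channels(cause, result, condition, intersect=intersect), **kwargs)

    def fit(self, seed: int | None = None) -> "TransferEntropyResults":
        """Compute TE time courses with significance for every
        (direction, Tc) of the design."""
        ss = np.random.SeedSequence(seed)
        jobs = [(d, tc) for d in self.directions for tc in self.tc_values]
        courses = {}
        for (direction, tc), child in zip(jobs, ss.spawn(len(jobs))):
            t_values = [
                t for t in self.dataset.grid.times if tc < t <= self.t_max + 1e-9
            ]
            courses[(direction, tc)] = te_timecourse(
                self.dataset,
                direction,
                tc,
                t_values,
                n_null=self.n_null,
                percentile=self.percentile,
                seed=child,
                min_cells=self.min_cells,
                null_method=self.null_method,
            )
        return TransferEntropyResults(self, courses, seed)


class TransferEntropyResults:
    """Fitted TE time courses and the resampling analyses built on them."""

    def __init__(self, model: TransferEntropyModel, courses: dict, seed) -> None:
        self.model = model
        self.courses = courses
        self.seed = seed
        self.table = pd.concat(
            [c.as_frame() for c in courses.values()], ignore_index=True
        )

    def course(self, direction: str, tc: float) -> TETimeCourse:
        return self.courses[(direction, float(tc))]

    def tesum(self, window: PeakWindow) -> float:
        """Point TEsum (sum of significant TE) over a peak window."""
        return tesum(self.course(window.direction, window.tc), window)

    def bootstrap_tesum(
        self,
        window: PeakWindow,
        n_boot: int = N_BOOT_DEFAULT,
        seed: int | None = None,
        **kwargs,
    ) -> TEsumEstimate:
        """Bootstrap mean and 5–95% range of the windowed TEsum."""
        return bootstrap_tesum(
            self.model.dataset,
            window,
            n_boot=n_boot,
            n_null=self.model.n_null,
            percentile=self.model.percentile,
            seed=seed,
            min_cells=self.model.min_cells,
            **kwargs,
        )

    def significant_fraction(self, direction: str) -> float:
        sub = self.table[self.table.direction == direction]
        return float(sub.significant.mean()) if len(sub) else float("nan")

    def summary(self) -> str:
        """Plain-text summary in the style of regression results tables."""
        tab = self.table
        n = self.model.dataset.n_cells
        lines = [
            "Transfer entropy results",
            "=" * 64,
            f"cells: {n}    null resamples: {self.model.n_null}"
            f"    threshold percentile: {self.model.percentile:g}",
            f"directions: {', '.join(self.model.directions)}"
            f"    Tc values: {len(self.model.tc_values)}"
            f"    t range: <= {self.model.t_max:g} min",
            "-" * 64,
            f"{'direction':>9} {'n queries':>10} {'n signif':>9} "
            f"{'max TE (nats)':>14} {'argmax (Tc,t)':>16}",
        ]
        for d in self.model.directions:
            sub = tab[tab.direction == d]
            imax = sub.te.idxmax()
            row = sub.loc[imax]
            lines.append(
                f"{d:>9} {len(sub):>10d} {int(sub.significant.sum()):>9d} "
                f"{row.te:>14.4f} {f'({row.tc:g},{row.t:g})':>16}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def to_csv(self, path) -> str:
        """Write the tidy (direction, tc, t, te, threshold, significant)
        table."""
        self.table.to_csv(path, index=False)
        return str(path)

    def plot_timecourse(self, direction: str = "fw", tc_values=None, ax=None):
        """Significant-TE-only time courses, one line per Tc."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tcs = tc_values if tc_values is not None else self.model.tc_values
        for tc in tcs:
            frame = self.course(direction, tc).as_frame()
            y = np.where(frame.significant, frame.te, np.nan)
            ax.plot(frame.t, y, label=f"Tc={tc:g}")
        ax.set_xlabel("t (min)")
        ax.set_ylabel("TE (nats)")
        ax.set_title(f"{direction} TE time courses")
        if len(tcs) <= 8:
            ax.legend(fontsize="small")
        return ax
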