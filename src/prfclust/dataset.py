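"""Containers for per-site BOLD time series on a 2D cortical sheet.

A :class:`SheetDataset` holds one hemisphere's worth of recording sites:
their 2D sheet coordinates (mm, standing in for a flattened cortical
surface), one time series per site per run, run labels (bar width and sweep
directions), and — for synthetic data — the ground-truth pRF parameters each
series was generated from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .prf_model import HEMISPHERES, PRFParams


@dataclass(frozen=True)
class Run:
    """One scanning run: all sites' series for one bar width.

    ``series`` has shape (n_sites, n_timepoints).
    """

    width_deg: float
    series: np.ndarray
    run_id: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.series, dtype=float)
        if s.ndim != 2:
            raise ValueError("series must be (n_sites, n_timepoints)")
        object.__setattr__(self, "series", s)


@dataclass(frozen=True)
class SheetDataset:
    """Per-site time series plus sheet geometry and optional ground truth."""

    coords_mm: np.ndarray
    runs: tuple[Run, ...]
    tr_s: float = 2.0
    hemisphere: str = "left"
    site_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    ground_truth: tuple[PRFParams, ...] | None = None
    region_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords_mm, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords_mm must be (n_sites, 2)")
        object.__setattr__(self, "coords_mm", coords)
        object.__setattr__(self, "runs", tuple(self.runs))
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        n = len(coords)
        for r in self.runs:
            if r.series.shape[0] != n:
                raise ValueError("every run must cover all sites")
        if self.site_ids is None:
            object.__setattr__(self, "site_ids", np.arange(n))
        else:
            object.__setattr__(self, "site_ids", np.asarray(self.site_ids))
        if self.ground_truth is not None:
            gt = tuple(self.ground_truth)
            if len(gt) != n:
                raise ValueError("ground_truth must have one entry per site")
            object.__setattr__(self, "ground_truth", gt)

    @property
    def n_sites(self) -> int:
        return len(self.coords_mm)

    @property
    def widths(self) -> tuple[float, ...]:
        """Distinct bar widths present, ascending."""
        return tuple(sorted({r.width_deg for r in self.runs}))

    def runs_for_widths(self, widths: Iterable[float]) -> "SheetDataset":
        """Subset of runs whose bar width is in ``widths``."""
        widths = set(widths)
        kept = tuple(r for r in self.runs if r.width_deg in widths)
        missing = widths - {r.width_deg for r in kept}
        if missing:
            raise ValueError(f"no runs for bar width(s): {sorted(missing)}")
        return replace(self, runs=kept)

    def select_sites(self, index: Sequence[int] | np.ndarray) -> "SheetDataset":
        index = np.asarray(index)
        gt = None
        if self.ground_truth is not None:
            gt = tuple(self.ground_truth[i] for i in index)
        labels = None if self.region_labels is None else self.region_labels[index]
        return replace(
            self,
            coords_mm=self.coords_mm[index],
            runs=tuple(replace(r, series=r.series[index]) for r in self.runs),
            site_ids=self.site_ids[index],
            ground_truth=gt,
            region_labels=labels,
        )

    def with_runs(self, runs: Sequence[Run]) -> "SheetDataset":
        return replace(self, runs=tuple(runs))
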