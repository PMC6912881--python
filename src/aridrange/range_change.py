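"""Current-vs-future range comparison: gain/loss classes and net change.

Comparing the current suitable-habitat map with a future one classifies each
cell by its (current, future) bit pair — stable suitable, habitat gain
(unsuitable now, suitable later), habitat loss (the reverse), or stable
unsuitable.  Percentages are reported relative to the *current* suitable
area, so a complete loss is exactly -100% net change, and the headline net
statistic is ``gain% - loss%``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid_core import AlignmentError, GridSpec, RasterLayer
from .ensemble_consensus import BinaryMap

__all__ = [
    "RangeChangeMap",
    "ChangeSummary",
    "classify_change",
    "change_summary",
    "CLASS_CODES",
]

logger = logging.getLogger(__name__)

# raster class coding for written change maps
CLASS_CODES = {
    "stable_unsuitable": 0,
    "gain": 1,
    "loss": 2,
    "stable_suitable": 3,
}


@dataclass
class RangeChangeMap:
    """Per-cell change class; codes per CLASS_CODES, nodata masked."""

    grid: GridSpec
    classes: np.ndarray
    mask: np.ndarray

    def count(self, name: str) -> int:
        return int((self.classes[~self.mask] == CLASS_CODES[name]).sum())

    def as_layer(self, name: str = "range_change") -> RasterLayer:
        return RasterLayer(
            name, self.grid, self.classes.astype(float), self.mask.copy()
        )


@dataclass
class ChangeSummary:
    stable_suitable: int
    gain: int
    loss: int
    stable_unsuitable: int
    current_range_cells: int
    gain_pct: float
    loss_pct: float
    net_pct: float
    cell_area: float

    @property
    def current_area(self) -> float:
        return self.current_range_cells * self.cell_area

    @property
    def future_range_cells(self) -> int:
        return self.stable_suitable + self.gain

    def to_dict(self) -> dict:
        return {
            "stable_suitable": self.stable_suitable,
            "gain": self.gain,
            "loss": self.loss,
            "stable_unsuitable": self.stable_unsuitable,
            "current_range_cells": self.current_range_cells,
            "future_range_cells": self.future_range_cells,
            "gain_pct": self.gain_pct,
            "loss_pct": self.loss_pct,
            "net_pct": self.net_pct,
            "cell_area": self.cell_area,
            "current_area": self.current_area,
        }


def classify_change(current: BinaryMap, future: BinaryMap) -> RangeChangeMap:
    """Classify every off-mask cell by its (current, future) suitability pair.

    The union of the two nodata masks is applied.
    """
    if current.grid != future.grid:
        raise AlignmentError("current and future maps must share one grid")
    mask = current.mask | future.mask
    cur = current.presence & ~mask
    fut = future.presence & ~mask
    classes = np.full(current.grid.shape, CLASS_CODES["stable_unsuitable"], dtype=np.int8)
    classes[cur & fut] = CLASS_CODES["stable_suitable"]
    classes[~cur & fut] = CLASS_CODES["gain"]
    classes[cur & ~fut] = CLASS_CODES["loss"]
    return RangeChangeMap(current.grid, classes, mask)


def change_summary(change: RangeChangeMap, cell_area: float = 1.0) -> ChangeSummary:
    """Counts, percentages (relative to current suitable area) and net change.

    With an empty current range the percentages are undefined and reported
    as NaN with a warning.
    """
    stable_s = change.count("stable_suitable")
    gain = change.count("gain")
    loss = change.count("loss")
    stable_u = change.count("stable_unsuitable")
    current = stable_s + loss
    if current == 0:
        logger.warning("empty current range: change percentages are undefined")
        gain_pct = loss_pct = net_pct = float("nan")
    else:
        gain_pct = 100.0 * gain / current
        loss_pct = 100.0 * loss / current
        net_pct = gain_pct - loss_pct
    return ChangeSummary(
        stable_suitable=stable_s,
        gain=gain,
        loss=loss,
        stable_unsuitable=stable_u,
        current_range_cells=current,
        gain_pct=gain_pct,
        loss_pct=loss_pct,
        net_pct=net_pct,
        cell_area=cell_area,
    )


def summaries_to_frame(rows: list[tuple[str, str, str, ChangeSummary]]) -> pd.DataFrame:
    """Tabulate (species, period, rcp, summary) rows — the machine twin of a
    published range-change bar chart."""
    return pd.DataFrame(
        [
            {"species": sp, "period": period, "rcp": rcp, **s.to_dict()}
            for sp, period, rcp, s in rows
        ]
    )
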