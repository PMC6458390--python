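"""Replicate-level measurement tables and per-time-point growth series.

A *measurement table* is a tidy :class:`pandas.DataFrame` with one row
per (sampling day, replicate) and canonical-unit columns::

    dag           sampling time, days after germination
    replicate     replicate identifier within the day
    area_mm2      basal secondary-xylem cross-section area, mm^2
    cell_count    secondary-xylem cells in the basal section
    extension_mm  longitudinal extension of secondary xylem, mm

:func:`summarize` collapses the table to per-day means with standard
errors for each measured quantity, and reconstructs the cone-volume
series from the area and extension means with quadrature-propagated
errors (the volume itself is never measured directly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import cone_volume
from .models import propagate_error

__all__ = ["GrowthSeries", "CANONICAL_COLUMNS", "summarize"]

CANONICAL_COLUMNS = ("dag", "replicate", "area_mm2", "cell_count", "extension_mm")

#: measurement-table column and unit per summarised quantity
QUANTITY_COLUMNS = {
    "area": ("area_mm2", "mm^2"),
    "cells": ("cell_count", "cells"),
    "extension": ("extension_mm", "mm"),
}


@dataclass
class GrowthSeries:
    """Per-time-point means and standard errors of one measured quantity."""

    times: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    quantity: str
    units: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if not (self.times.shape == self.mean.shape == self.sem.shape):
            raise ValueError("times, mean and sem must have equal lengths")
        if np.any(self.sem < 0):
            raise ValueError("sem must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dag": self.times, "mean": self.mean, "sem": self.sem}
        )


def _validate_table(table: pd.DataFrame):
    missing = [c for c in CANONICAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table is missing columns: {missing}")


def summarize(table: pd.DataFrame, expected_times=None) -> dict:
    """Collapse a measurement table to per-day growth series.

    Returns a dict with keys ``area``, ``cells``, ``extension`` and
    ``volume``. The volume series is cone_volume(mean area, mean
    extension) per day; its relative error is the quadrature sum of the
    relative errors of area and extension, since V = (1/3) a h is a
    product of the two measured quantities and an exact constant.

    ``expected_times`` (optional) lists sampling days that must be
    present; any that are absent raise a ValueError naming them.
    """
    _validate_table(table)
    if len(table) == 0:
        raise ValueError("measurement table is empty")
    if expected_times is not None:
        have = set(np.asarray(table["dag"], dtype=float))
        absent = sorted(t for t in np.asarray(expected_times, dtype=float)
                        if t not in have)
        if absent:
            raise ValueError(f"missing time points: {absent}")

    grouped = table.groupby("dag", sort=True)
    times = np.array(sorted(grouped.groups), dtype=float)
    series = {}
    for name, (col, units) in QUANTITY_COLUMNS.items():
        mean = grouped[col].mean().to_numpy(dtype=float)
        # SEM = s / sqrt(n); a single replicate carries no spread estimate
        sem = (grouped[col].std(ddof=1) / np.sqrt(grouped[col].count())).fillna(0.0)
        series[name] = GrowthSeries(times, mean, sem.to_numpy(dtype=float),
                                    quantity=name, units=units)

    a, h = series["area"], series["extension"]
    v_mean = np.empty_like(a.mean)
    v_sem = np.empty_like(a.mean)
    for i in range(times.size):
        if a.mean[i] > 0 and h.mean[i] > 0:
            v_mean[i], v_sem[i] = propagate_error(
                [(a.mean[i], a.sem[i]), (h.mean[i], h.sem[i])],
                operation="product", scale=1.0 / 3.0,
            )
        else:
            v_mean[i] = cone_volume(max(a.mean[i], 0.0), max(h.mean[i], 0.0))
            v_sem[i] = 0.0
    series["volume"] = GrowthSeries(times, v_mean, v_sem,
                                    quantity="volume", units="mm^3")
    return series
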