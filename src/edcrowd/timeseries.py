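"""Scoring snapshot streams and aggregating them into reporting views.

The reporting views mirror how ED crowding is usually summarised: the share
of observations in each crowding band per day, the weekday/weekend
contrast, and time-of-day windows (e.g. the morning-to-midnight block where
load peaks).

EDWIN observations with a saturated denominator (patients >= treatment
beds) cannot be banded by score; they are reported in a separate
``saturated`` column so the stated band percentages stay interpretable, and
every group's columns still sum to 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import HospitalConfig
from .indices import (
    EdwinLabel,
    NedocsLabel,
    compute_edwin,
    compute_nedocs,
)
from .simulate import SnapshotSeries

EDWIN_LABELS = [lab.name.lower() for lab in EdwinLabel]
NEDOCS_LABELS = [lab.name.lower() for lab in NedocsLabel]
SATURATED = "saturated"


@dataclass(frozen=True)
class IndexSeries:
    """Paired EDWIN/NEDOCS scores for an ordered snapshot stream.

    ``data`` columns: ``timestamp``, ``edwin_value``, ``edwin_valid``,
    ``edwin_label``, ``nedocs_value``, ``nedocs_label`` (labels as
    lowercase band names).
    """

    data: pd.DataFrame
    cadence: int

    def __len__(self) -> int:
        return len(self.data)


def score_series(
    series: SnapshotSeries,
    hospital: Optional[HospitalConfig] = None,
    variant: str = "standard",
) -> IndexSeries:
    """Apply both indices to every snapshot, preserving order and length."""
    h = hospital if hospital is not None else series.hospital
    rows = []
    for s in series:
        try:
            e = compute_edwin(s, h)
            n = compute_nedocs(s, h, variant=variant)
        except ValueError as err:
            raise ValueError(f"scoring failed at {s.timestamp}: {err}") from err
        rows.append(
            {
                "timestamp": s.timestamp,
                "edwin_value": e.value,
                "edwin_valid": e.valid,
                "edwin_label": e.label.name.lower(),
                "nedocs_value": n.value,
                "nedocs_label": n.label.name.lower(),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "timestamp", "edwin_value", "edwin_valid", "edwin_label",
            "nedocs_value", "nedocs_label",
        ],
    )
    return IndexSeries(data=df, cadence=series.cadence)


def _group_keys(ts: pd.Series, grouping: str) -> pd.Series:
    ts = pd.to_datetime(ts)
    if grouping == "per_day":
        return ts.dt.date.astype(str)
    if grouping == "weekpart":
        return np.where(ts.dt.weekday >= 5, "weekend", "weekday")
    if grouping == "hour_window":
        return ts.dt.hour
    raise ValueError(f"unknown grouping {grouping!r}")


def band_proportions(
    iseries: IndexSeries, index_name: str, grouping: str = "per_day"
) -> pd.DataFrame:
    """Percentage of observations in each crowding band, per group.

    Rows are groups (days, weekday/weekend, or hours of day), columns the
    scale's bands in severity order — plus a ``saturated`` column for EDWIN.
    Each row sums to 100 over observed ticks; empty groups are omitted with
    a warning.
    """
    index_name = index_name.upper()
    if index_name not in ("EDWIN", "NEDOCS"):
        raise ValueError(f"unknown index {index_name!r}")
    df = iseries.data
    if len(df) == 0:
        raise ValueError("empty series")
    keys = _group_keys(df["timestamp"], grouping)

    if index_name == "EDWIN":
        columns = EDWIN_LABELS + [SATURATED]
        lab = df["edwin_label"].where(df["edwin_valid"], SATURATED)
    else:
        columns = list(NEDOCS_LABELS)
        lab = df["nedocs_label"]

    out = {}
    for key, grp in lab.groupby(keys):
        if len(grp) == 0:  # pragma: no cover - defensive
            warnings.warn(f"group {key!r} has no observations; omitted")
            continue
        frac = grp.value_counts(normalize=True) * 100.0
        out[key] = [float(frac.get(c, 0.0)) for c in columns]
    table = pd.DataFrame.from_dict(out, orient="index", columns=columns)
    table.index.name = grouping
    return table.sort_index()


@dataclass(frozen=True)
class WindowSummary:
    """Band shares and score summaries inside a daily clock window."""

    start_hour: int
    end_hour: int
    n_ticks: int
    edwin_proportions: pd.Series
    nedocs_proportions: pd.Series
    edwin_mean: float
    edwin_max: float
    nedocs_mean: float
    nedocs_max: float

    @property
    def empty(self) -> bool:
        return self.n_ticks == 0


def window_summary(
    iseries: IndexSeries, start_hour: int, end_hour: int
) -> WindowSummary:
    """Summarise scores within ``[start_hour, end_hour)`` of each day.

    Means and maxima use valid values only (all NEDOCS values are valid;
    saturated EDWIN ticks are excluded).  A window containing no ticks
    yields an empty sentinel (``n_ticks == 0``, NaN summaries).
    """
    if not (0 <= start_hour < end_hour <= 24):
        raise ValueError(
            f"need 0 <= start_hour < end_hour <= 24, got [{start_hour}, {end_hour})"
        )
    df = iseries.data
    hours = pd.to_datetime(df["timestamp"]).dt.hour
    sel = df[(hours >= start_hour) & (hours < end_hour)]
    n = len(sel)
    if n == 0:
        nan = float("nan")
        empty_e = pd.Series(0.0, index=EDWIN_LABELS + [SATURATED])
        empty_n = pd.Series(0.0, index=NEDOCS_LABELS)
        return WindowSummary(start_hour, end_hour, 0, empty_e, empty_n,
                             nan, nan, nan, nan)

    e_lab = sel["edwin_label"].where(sel["edwin_valid"], SATURATED)
    e_prop = (
        e_lab.value_counts(normalize=True)
        .reindex(EDWIN_LABELS + [SATURATED], fill_value=0.0) * 100.0
    )
    n_prop = (
        sel["nedocs_label"].value_counts(normalize=True)
        .reindex(NEDOCS_LABELS, fill_value=0.0) * 100.0
    )
    e_valid = sel.loc[sel["edwin_valid"], "edwin_value"]
    nan = float("nan")
    return WindowSummary(
        start_hour=start_hour,
        end_hour=end_hour,
        n_ticks=n,
        edwin_proportions=e_prop,
        nedocs_proportions=n_prop,
        edwin_mean=float(e_valid.mean()) if len(e_valid) else nan,
        edwin_max=float(e_valid.max()) if len(e_valid) else nan,
        nedocs_mean=float(sel["nedocs_value"].mean()),
        nedocs_max=float(sel["nedocs_value"].max()),
    )
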