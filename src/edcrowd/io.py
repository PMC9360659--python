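"""Snapshot CSV round-tripping, scored-output files and run manifests.

Snapshot CSV schema (header mandatory, one row per cadence tick)::

    timestamp,n_white,n_green,n_yellow,n_red,boarding,vent,
    longest_admit_wait_h,last_bed_time_h

Timestamps are ISO-8601, timezone-naive local clock time; wait-time columns
are hours.  Reading validates every row against the snapshot invariants and
reports offending line numbers.  Duplicate timestamps are rejected;
out-of-order rows are sorted with a warning, or rejected in strict mode;
gaps are permitted and logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime
from typing import Optional

import pandas as pd

from .config import HospitalConfig, SimulationConfig
from .indices import EDSnapshot
from .simulate import SnapshotSeries
from .timeseries import IndexSeries

log = logging.getLogger("edcrowd")

SNAPSHOT_COLUMNS = [
    "timestamp", "n_white", "n_green", "n_yellow", "n_red",
    "boarding", "vent", "longest_admit_wait_h", "last_bed_time_h",
]


def write_snapshots(series: SnapshotSeries, path: str) -> None:
    """Write a snapshot series to CSV (lossless round-trip)."""
    df = series.to_dataframe()
    df["timestamp"] = df["timestamp"].map(lambda t: t.isoformat())
    # %.17g guarantees float64 round-trips through text exactly
    df.to_csv(path, index=False, float_format="%.17g")


def read_snapshots(
    path: str,
    hospital: Optional[HospitalConfig] = None,
    strict: bool = False,
) -> SnapshotSeries:
    """Read and validate a snapshot CSV into a ``SnapshotSeries``.

    Malformed rows raise ``ValueError`` naming the 1-based file line (the
    header is line 1).  ``strict`` rejects out-of-order timestamps instead
    of sorting.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SNAPSHOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    snapshots = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        try:
            ts = datetime.fromisoformat(str(row.timestamp))
        except ValueError as err:
            raise ValueError(
                f"{path}:{line}: bad timestamp {row.timestamp!r}: {err}"
            ) from None
        try:
            snap = EDSnapshot(
                timestamp=ts,
                n_white=int(row.n_white),
                n_green=int(row.n_green),
                n_yellow=int(row.n_yellow),
                n_red=int(row.n_red),
                boarding=int(row.boarding),
                vent=int(row.vent),
                longest_admit_wait=float(row.longest_admit_wait_h),
                last_bed_time=float(row.last_bed_time_h),
            )
        except ValueError as err:
            raise ValueError(f"{path}:{line}: {err}") from None
        snapshots.append(snap)
    if not snapshots:
        raise ValueError(f"{path}: no snapshot rows")

    times = [s.timestamp for s in snapshots]
    if len(set(times)) != len(times):
        dup = max(set(times), key=times.count)
        raise ValueError(f"{path}: duplicate timestamp {dup.isoformat()}")
    if times != sorted(times):
        if strict:
            raise ValueError(f"{path}: timestamps out of order (strict mode)")
        log.warning("%s: timestamps out of order; sorting", path)
        snapshots.sort(key=lambda s: s.timestamp)
        times = [s.timestamp for s in snapshots]

    if len(times) > 1:
        deltas = {
            int((b - a).total_seconds()) for a, b in zip(times, times[1:])
        }
        cadence = min(deltas)
        if len(deltas) > 1:
            log.warning("%s: gaps in the snapshot grid (deltas %s)", path,
                        sorted(deltas))
    else:
        cadence = 900
    return SnapshotSeries(
        snapshots=snapshots,
        hospital=hospital if hospital is not None else HospitalConfig(),
        start=times[0],
        cadence=cadence,
    )


def write_scored(iseries: IndexSeries, series: SnapshotSeries, path: str) -> None:
    """Write snapshot columns plus index scores/labels to CSV."""
    snap = series.to_dataframe()
    snap["timestamp"] = snap["timestamp"].map(lambda t: t.isoformat())
    scored = iseries.data.drop(columns=["timestamp"]).reset_index(drop=True)
    pd.concat([snap.reset_index(drop=True), scored], axis=1).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_scored(path: str, cadence: Optional[int] = None) -> IndexSeries:
    """Read a scored CSV back into an ``IndexSeries``."""
    df = pd.read_csv(path, float_precision="round_trip")
    needed = ["timestamp", "edwin_value", "edwin_valid", "edwin_label",
              "nedocs_value", "nedocs_label"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if cadence is None:
        if len(df) > 1:
            cadence = int(
                (df["timestamp"].iloc[1] - df["timestamp"].iloc[0]).total_seconds()
            )
        else:
            cadence = 900
    return IndexSeries(data=df[needed].copy(), cadence=cadence)


def read_capacity_table(path: str) -> pd.DataFrame:
    """Read a per-department bed census CSV."""
    df = pd.read_csv(path)
    needed = {"department", "day_hospital_beds", "hospitalization_beds"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def config_hash(config: SimulationConfig) -> str:
    """Stable short hash of a scenario, for run manifests."""
    text = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_manifest(path: str, config: SimulationConfig) -> None:
    """Record seed, config hash and the full scenario next to an output."""
    manifest = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "config": config.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
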