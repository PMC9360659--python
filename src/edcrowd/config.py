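"""Static configuration objects: hospital capacity and simulation scenarios.

The hospital side captures what the crowding indices need to know about the
site: how many ED treatment beds exist (``B_T`` in EDWIN, ``ED Bds`` in
NEDOCS), how many attending physicians are on duty (``N_a``), and how many
accredited inpatient beds the hospital operates (``H Bds``), optionally
backed by a per-department capacity table whose grand total must agree.

The simulation side describes a synthetic patient-flow scenario: arrival
intensity with diurnal and day-of-week shape, the triage acuity mix, service
and boarding time scales, and a seed.  Defaults emulate a large urban ED
with roughly 300 arrivals per day, busier from mid-morning to midnight and
during midweek.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from importlib import resources
from typing import Optional, Sequence

import pandas as pd
import yaml

ACUITIES = ("white", "green", "yellow", "red")

#: Default diurnal multipliers (hour 0..23): quiet overnight, ramp through
#: the morning, sustained load from 09:00 to midnight.
DEFAULT_DIURNAL = (
    0.45, 0.45, 0.45, 0.45, 0.45, 0.45,   # 00-05
    0.80, 0.80, 1.10,                      # 06-08
    1.30, 1.30, 1.30, 1.30, 1.30, 1.30,   # 09-14
    1.30, 1.30, 1.30, 1.30, 1.30, 1.30,   # 15-20
    1.30, 1.30, 1.00,                      # 21-23
)

#: Default day-of-week multipliers, Monday..Sunday: midweek above weekend.
DEFAULT_WEEKDAY = (1.10, 1.15, 1.15, 1.15, 1.10, 0.80, 0.75)


def builtin_capacity_table_path() -> str:
    """Path of the packaged per-department accredited-bed census CSV."""
    return str(resources.files("edcrowd.data").joinpath("cardarelli_beds.csv"))


@dataclass(frozen=True)
class HospitalConfig:
    """Static site capacity used by the crowding indices.

    Parameters
    ----------
    ed_beds:
        ED treatment beds (``B_T`` / ``ED Bds``).
    physicians:
        Attending physicians on duty (``N_a``).
    hospital_beds:
        Accredited inpatient beds hospital-wide (``H Bds``).
    capacity_table:
        Optional per-department table with columns ``department``,
        ``day_hospital_beds``, ``hospitalization_beds``.  When given, its
        grand total must equal ``hospital_beds``.
    """

    ed_beds: int = 40
    physicians: int = 4
    hospital_beds: int = 1072
    capacity_table: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.ed_beds < 1:
            raise ValueError(f"ed_beds must be >= 1, got {self.ed_beds}")
        if self.physicians < 1:
            raise ValueError(f"physicians must be >= 1, got {self.physicians}")
        if self.hospital_beds < 1:
            raise ValueError(f"hospital_beds must be >= 1, got {self.hospital_beds}")
        if self.capacity_table is not None:
            from .indices import total_accredited_beds

            _, _, grand = total_accredited_beds(self.capacity_table)
            if grand != self.hospital_beds:
                raise ValueError(
                    f"hospital_beds={self.hospital_beds} does not match the "
                    f"capacity table grand total {grand}"
                )

    @classmethod
    def from_capacity_csv(
        cls, path: str, ed_beds: int = 40, physicians: int = 4
    ) -> "HospitalConfig":
        """Build a config whose ``hospital_beds`` is the table grand total."""
        from .indices import total_accredited_beds

        table = pd.read_csv(path)
        _, _, grand = total_accredited_beds(table)
        return cls(
            ed_beds=ed_beds,
            physicians=physicians,
            hospital_beds=grand,
            capacity_table=table,
        )

    @classmethod
    def default_site(cls) -> "HospitalConfig":
        """The packaged reference site: 40 ED beds, 4 physicians, 1072 beds."""
        return cls.from_capacity_csv(builtin_capacity_table_path())


def _as_tuple(x: Sequence[float], n: int, name: str) -> tuple:
    t = tuple(float(v) for v in x)
    if len(t) != n:
        raise ValueError(f"{name} must have {n} entries, got {len(t)}")
    if any(v < 0 for v in t):
        raise ValueError(f"{name} entries must be nonnegative")
    return t


@dataclass(frozen=True)
class SimulationConfig:
    """A synthetic ED patient-flow scenario.

    Arrival intensity at time ``t`` is
    ``base_arrival_rate * diurnal_profile[hour(t)] * weekday_profile[weekday(t)]``
    in patients/hour.  Each arrival draws a triage acuity from ``acuity_mix``,
    a treatment duration from an exponential (or lognormal) law with the
    acuity's mean, an admission indicator, a boarding duration when admitted,
    and a stable ventilation flag.
    """

    days: int = 7
    cadence: int = 900  # seconds between snapshots
    base_arrival_rate: float = 12.5  # patients/hour before profile shaping
    diurnal_profile: tuple = DEFAULT_DIURNAL
    weekday_profile: tuple = DEFAULT_WEEKDAY  # Monday..Sunday
    acuity_mix: tuple = (0.05, 0.55, 0.32, 0.08)  # white, green, yellow, red
    mean_los_by_acuity: tuple = (0.5, 1.1, 1.9, 2.6)  # hours
    admit_prob_by_acuity: tuple = (0.01, 0.05, 0.25, 0.70)
    mean_boarding_time: float = 1.5  # hours
    vent_prob: float = 0.02
    los_distribution: str = "exponential"  # or "lognormal"
    los_sigma: float = 0.5  # log-sd for the lognormal option
    start: datetime = field(default_factory=lambda: datetime(2016, 3, 14))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError(f"days must be >= 1, got {self.days}")
        if self.cadence <= 0 or 86400 % self.cadence != 0:
            raise ValueError(
                f"cadence must be a positive divisor of 86400, got {self.cadence}"
            )
        object.__setattr__(
            self, "diurnal_profile",
            _as_tuple(self.diurnal_profile, 24, "diurnal_profile"),
        )
        object.__setattr__(
            self, "weekday_profile",
            _as_tuple(self.weekday_profile, 7, "weekday_profile"),
        )
        object.__setattr__(
            self, "acuity_mix", _as_tuple(self.acuity_mix, 4, "acuity_mix")
        )
        object.__setattr__(
            self, "mean_los_by_acuity",
            _as_tuple(self.mean_los_by_acuity, 4, "mean_los_by_acuity"),
        )
        object.__setattr__(
            self, "admit_prob_by_acuity",
            _as_tuple(self.admit_prob_by_acuity, 4, "admit_prob_by_acuity"),
        )
        if abs(sum(self.acuity_mix) - 1.0) > 1e-9:
            raise ValueError(
                f"acuity_mix must sum to 1, got {sum(self.acuity_mix)!r}"
            )
        if any(p > 1 for p in self.admit_prob_by_acuity):
            raise ValueError("admit probabilities must be <= 1")
        if self.base_arrival_rate < 0:
            raise ValueError("base_arrival_rate must be >= 0")
        if self.mean_boarding_time < 0:
            raise ValueError("mean_boarding_time must be >= 0")
        if not 0 <= self.vent_prob <= 1:
            raise ValueError("vent_prob must be in [0, 1]")
        if self.los_distribution not in ("exponential", "lognormal"):
            raise ValueError(
                f"unknown los_distribution {self.los_distribution!r}"
            )

    @property
    def n_snapshots(self) -> int:
        return self.days * 86400 // self.cadence

    def to_dict(self) -> dict:
        d = {
            "days": self.days,
            "cadence": self.cadence,
            "base_arrival_rate": self.base_arrival_rate,
            "diurnal_profile": list(self.diurnal_profile),
            "weekday_profile": list(self.weekday_profile),
            "acuity_mix": list(self.acuity_mix),
            "mean_los_by_acuity": list(self.mean_los_by_acuity),
            "admit_prob_by_acuity": list(self.admit_prob_by_acuity),
            "mean_boarding_time": self.mean_boarding_time,
            "vent_prob": self.vent_prob,
            "los_distribution": self.los_distribution,
            "los_sigma": self.los_sigma,
            "start": self.start.isoformat(),
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "start" in d and isinstance(d["start"], str):
            d["start"] = datetime.fromisoformat(d["start"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
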