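"""EDWIN and NEDOCS crowding indices and their classification bands.

EDWIN (Emergency Department Work Index) measures acuity-weighted patient
load per physician per free treatment bed:

    EDWIN = sum_i(n_i * t_i) / (N_a * (B_T - B_A))

where ``n_i`` is the number of patients in triage category ``i``, ``t_i``
the category weight (white 1, green 2, yellow 3, red 4), ``N_a`` the
attending physicians on duty, ``B_T`` the treatment beds and ``B_A`` the
patients present.  Below 1.5 the ED is active but manageable, 1.5-2 busy,
above 2 crowded.  When the ED holds as many patients as it has beds the
denominator vanishes or turns negative; such scores are flagged invalid and
classified as crowded (the department is at or over physical capacity).

NEDOCS (National Emergency Department Overcrowding Scale) is a linear score
over occupancy, boarding burden, ventilated patients and two wait times.
The standard additive form is

    NEDOCS = -20 + 85.8*(TP/ED_beds) + 600*(Brdg/H_beds)
             + 13.4*Vent + 0.93*LongAdmt + 5.64*LBT

with bands normal [<50), busy [50,101), overcrowded [101,141), severe
overcrowding [141,180] and disaster (>180).  A "literal" variant with a
multiplicative first term ``-20*85.8*(TP/ED_beds)`` is provided for
auditing sources that print the formula that way; it produces large
negative scores on busy departments and is not the default.
"""

from __future__ import annotations

import math
import numbers
from dataclasses import dataclass, field
from datetime import datetime
from enum import IntEnum
from typing import FrozenSet, Tuple

import pandas as pd

from .config import ACUITIES, HospitalConfig

#: Triage weights t_i, white..red.
TRIAGE_WEIGHTS = {"white": 1, "green": 2, "yellow": 3, "red": 4}

FLAG_DENOMINATOR_NONPOSITIVE = "denominator_nonpositive"
FLAG_NEGATIVE_SCORE = "negative_score"


class EdwinLabel(IntEnum):
    """EDWIN crowding bands, ordered by severity."""

    ACTIVE_MANAGEABLE = 0
    BUSY = 1
    CROWDED = 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name.lower()


class NedocsLabel(IntEnum):
    """NEDOCS crowding bands, ordered by severity."""

    NORMAL = 0
    BUSY = 1
    OVERCROWDED = 2
    SEVERE_OVERCROWDING = 3
    DISASTER = 4

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name.lower()


@dataclass(frozen=True)
class EDSnapshot:
    """One 15-minute observation of ED state.

    Counts are patients *present* (waiting room, treatment or boarding) per
    triage colour code; ``boarding`` is admitted patients held in the ED
    awaiting an inpatient bed; ``vent`` is ventilated patients present;
    ``longest_admit_wait`` is the longest current boarding wait in hours;
    ``last_bed_time`` is the waiting-room (door-to-bed) duration, in hours,
    of the most recent patient placed in a treatment bed.
    """

    timestamp: datetime
    n_white: int
    n_green: int
    n_yellow: int
    n_red: int
    boarding: int
    vent: int
    longest_admit_wait: float  # hours
    last_bed_time: float  # hours

    def __post_init__(self) -> None:
        for name in ("n_white", "n_green", "n_yellow", "n_red", "boarding", "vent"):
            v = getattr(self, name)
            if isinstance(v, bool) or not isinstance(v, numbers.Integral) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        total = self.total_patients
        if self.boarding > total:
            raise ValueError(
                f"boarding ({self.boarding}) exceeds patients present ({total})"
            )
        if self.vent > total:
            raise ValueError(
                f"vent ({self.vent}) exceeds patients present ({total})"
            )
        for name in ("longest_admit_wait", "last_bed_time"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def total_patients(self) -> int:
        """Patients present in the ED (B_A, also NEDOCS' TP)."""
        return self.n_white + self.n_green + self.n_yellow + self.n_red

    @property
    def counts(self) -> Tuple[int, int, int, int]:
        return (self.n_white, self.n_green, self.n_yellow, self.n_red)


@dataclass(frozen=True)
class IndexValue:
    """A scored snapshot for one index."""

    index_name: str  # "EDWIN" or "NEDOCS"
    value: float
    valid: bool
    flags: FrozenSet[str] = field(default_factory=frozenset)
    label: IntEnum = EdwinLabel.ACTIVE_MANAGEABLE


def classify_edwin(value: float, valid: bool = True) -> EdwinLabel:
    """Band an EDWIN score: <1.5 active/manageable, 1.5-2 busy, >2 crowded.

    An invalid score (saturated denominator, B_T <= B_A) classifies as
    crowded: the ED is at or over its physical bed capacity.
    """
    if not valid:
        return EdwinLabel.CROWDED
    if value < 1.5:
        return EdwinLabel.ACTIVE_MANAGEABLE
    if value <= 2.0:
        return EdwinLabel.BUSY
    return EdwinLabel.CROWDED


def classify_nedocs(value: float) -> NedocsLabel:
    """Band a NEDOCS score.

    Left-closed/right-open at 50, 101 and 141; severe overcrowding covers
    [141, 180] and disaster is strictly above 180.  Negative scores band as
    normal.
    """
    if value < 50:
        return NedocsLabel.NORMAL
    if value < 101:
        return NedocsLabel.BUSY
    if value < 141:
        return NedocsLabel.OVERCROWDED
    if value <= 180:
        return NedocsLabel.SEVERE_OVERCROWDING
    return NedocsLabel.DISASTER


def compute_edwin(s: EDSnapshot, h: HospitalConfig) -> IndexValue:
    """Score one snapshot with EDWIN.

    With a positive denominator the score is valid and nonnegative.  When
    B_T - B_A <= 0 the score carries the ``denominator_nonpositive`` flag,
    ``valid`` is False and the label is crowded; the raw signed ratio is
    kept for a negative denominator and NaN marks the exactly-zero case.
    """
    numerator = sum(
        TRIAGE_WEIGHTS[a] * c for a, c in zip(ACUITIES, s.counts)
    )
    free_beds = h.ed_beds - s.total_patients
    denominator = h.physicians * free_beds
    if denominator > 0:
        value = numerator / denominator
        return IndexValue("EDWIN", value, True, frozenset(), classify_edwin(value))
    value = numerator / denominator if denominator < 0 else math.nan
    return IndexValue(
        "EDWIN",
        value,
        False,
        frozenset({FLAG_DENOMINATOR_NONPOSITIVE}),
        classify_edwin(value, valid=False),
    )


def compute_nedocs(
    s: EDSnapshot, h: HospitalConfig, variant: str = "standard"
) -> IndexValue:
    """Score one snapshot with NEDOCS.

    ``variant="standard"`` uses the additive Weiss form (default);
    ``variant="literal"`` multiplies the occupancy term by -20*85.8.
    Negative scores carry the ``negative_score`` flag but remain valid and
    band as normal.
    """
    if variant not in ("standard", "literal"):
        raise ValueError(f"unknown NEDOCS variant {variant!r}")
    occupancy = s.total_patients / h.ed_beds
    tail = (
        600.0 * (s.boarding / h.hospital_beds)
        + 13.4 * s.vent
        + 0.93 * s.longest_admit_wait
        + 5.64 * s.last_bed_time
    )
    if variant == "standard":
        value = -20.0 + 85.8 * occupancy + tail
    else:
        value = -20.0 * 85.8 * occupancy + tail
    flags = frozenset({FLAG_NEGATIVE_SCORE}) if value < 0 else frozenset()
    return IndexValue("NEDOCS", value, True, flags, classify_nedocs(value))


def total_accredited_beds(table: pd.DataFrame) -> Tuple[int, int, int]:
    """Column sums of a per-department bed census.

    Returns ``(day_hospital_total, hospitalization_total, grand_total)``.
    Entries must be nonnegative integers.
    """
    required = {"day_hospital_beds", "hospitalization_beds"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"capacity table missing columns: {sorted(missing)}")
    if len(table) == 0:
        return (0, 0, 0)
    for col in sorted(required):
        vals = table[col]
        if (vals < 0).any():
            raise ValueError(f"negative bed count in column {col!r}")
        if not (vals == vals.astype(int)).all():
            raise ValueError(f"non-integer bed count in column {col!r}")
    day = int(table["day_hospital_beds"].sum())
    hosp = int(table["hospitalization_beds"].sum())
    return (day, hosp, day + hosp)
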