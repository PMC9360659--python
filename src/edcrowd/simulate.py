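"""Synthetic ED patient-flow simulator.

Generates snapshot streams with the statistical structure the crowding
analysis assumes, standing in for a hospital information-system feed.

Arrivals follow a nonhomogeneous Poisson process whose hourly intensity is
``base_arrival_rate * diurnal_profile[hour] * weekday_profile[weekday]``,
realised by thinning against the maximum rate.  Each arriving patient draws
a triage acuity, a treatment duration, an admission indicator (admitted
patients board in their treatment bed until an inpatient bed frees), a
boarding duration, and a stable ventilation flag.  Patients wait in a
virtual waiting room while all treatment beds are occupied; the waiting
queue is acuity-priority (red before yellow before green before white),
FIFO within acuity.  At every cadence tick the simulator emits an
``EDSnapshot`` with per-code census, boarding and ventilated counts, the
longest current boarding wait, and the door-to-bed time of the most
recently seated patient.

All randomness flows from one seeded ``numpy`` generator, so a single
integer seed reproduces a run bit for bit.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import List

import numpy as np
import pandas as pd

from .config import HospitalConfig, SimulationConfig
from .indices import EDSnapshot


def arrival_rate(t: datetime, config: SimulationConfig) -> float:
    """Instantaneous arrival intensity (patients/hour) at clock time ``t``."""
    return (
        config.base_arrival_rate
        * config.diurnal_profile[t.hour]
        * config.weekday_profile[t.weekday()]
    )


@dataclass(frozen=True)
class SnapshotSeries:
    """An ordered, evenly spaced stream of ED snapshots."""

    snapshots: List[EDSnapshot]
    hospital: HospitalConfig
    start: datetime
    cadence: int  # seconds

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "timestamp": s.timestamp,
                "n_white": s.n_white,
                "n_green": s.n_green,
                "n_yellow": s.n_yellow,
                "n_red": s.n_red,
                "boarding": s.boarding,
                "vent": s.vent,
                "longest_admit_wait_h": s.longest_admit_wait,
                "last_bed_time_h": s.last_bed_time,
            }
            for s in self.snapshots
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "timestamp", "n_white", "n_green", "n_yellow", "n_red",
                "boarding", "vent", "longest_admit_wait_h", "last_bed_time_h",
            ],
        )


class _Patient:
    __slots__ = (
        "acuity", "arrival_s", "los_s", "admitted", "boarding_s",
        "ventilated", "state", "boarding_start_s",
    )

    def __init__(self, acuity, arrival_s, los_s, admitted, boarding_s, ventilated):
        self.acuity = acuity  # 0 white .. 3 red
        self.arrival_s = arrival_s
        self.los_s = los_s
        self.admitted = admitted
        self.boarding_s = boarding_s
        self.ventilated = ventilated
        self.state = "waiting"
        self.boarding_start_s = None


def _draw_arrivals(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Arrival offsets (seconds from start) by thinning a homogeneous process."""
    rate_max = (
        config.base_arrival_rate
        * max(config.diurnal_profile)
        * max(config.weekday_profile)
    )
    if rate_max <= 0:
        return np.empty(0)
    rate_max_per_s = rate_max / 3600.0
    horizon = config.days * 86400
    times = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate_max_per_s)
        if t >= horizon:
            break
        clock = config.start + timedelta(seconds=t)
        if rng.random() * rate_max <= arrival_rate(clock, config):
            times.append(t)
    return np.asarray(times)


def _draw_los_seconds(
    config: SimulationConfig, acuity: int, rng: np.random.Generator
) -> float:
    mean_h = config.mean_los_by_acuity[acuity]
    if config.los_distribution == "exponential":
        los_h = rng.exponential(mean_h) if mean_h > 0 else 0.0
    else:
        # lognormal parameterised so the arithmetic mean equals mean_h
        sigma = config.los_sigma
        mu = np.log(mean_h) - sigma**2 / 2 if mean_h > 0 else -np.inf
        los_h = rng.lognormal(mu, sigma) if mean_h > 0 else 0.0
    return los_h * 3600.0


def simulate(config: SimulationConfig, hospital: HospitalConfig) -> SnapshotSeries:
    """Run the event-driven simulation and emit one snapshot per cadence tick.

    The series has exactly ``days * 86400 / cadence`` snapshots, at
    ``start + k*cadence`` for ``k = 0 .. n-1``.  Every simulated patient is
    either present at a tick or has departed; counts are conserved.
    """
    rng = np.random.default_rng(config.seed)
    arrivals = _draw_arrivals(config, rng)

    # Per-patient attribute draws, in arrival order.
    patients = []
    for t in arrivals:
        acuity = int(rng.choice(4, p=config.acuity_mix))
        los_s = _draw_los_seconds(config, acuity, rng)
        admitted = rng.random() < config.admit_prob_by_acuity[acuity]
        boarding_s = (
            rng.exponential(config.mean_boarding_time) * 3600.0 if admitted else 0.0
        )
        ventilated = rng.random() < config.vent_prob
        patients.append(_Patient(acuity, t, los_s, admitted, boarding_s, ventilated))

    events = []  # (time_s, seq, kind, patient)
    seq = 0
    for p in patients:
        events.append((p.arrival_s, seq, "arrival", p))
        seq += 1
    heapq.heapify(events)

    free_beds = hospital.ed_beds
    # waiting queues indexed by acuity; seated red-first, FIFO within acuity
    waiting = [deque() for _ in range(4)]
    present: set = set()
    last_bed_wait_h = 0.0

    def seat(p: _Patient, now: float) -> None:
        nonlocal seq, last_bed_wait_h
        p.state = "treatment"
        last_bed_wait_h = (now - p.arrival_s) / 3600.0
        heapq.heappush(events, (now + p.los_s, seq, "service_end", p))
        seq += 1

    def seat_from_queue(now: float) -> None:
        nonlocal free_beds
        while free_beds > 0:
            for acuity in (3, 2, 1, 0):
                if waiting[acuity]:
                    free_beds -= 1
                    seat(waiting[acuity].popleft(), now)
                    break
            else:
                return

    def depart(p: _Patient) -> None:
        nonlocal free_beds
        present.discard(p)
        free_beds += 1

    n_ticks = config.n_snapshots
    tick_times = [k * config.cadence for k in range(n_ticks)]
    snapshots: List[EDSnapshot] = []

    for tick_s in tick_times:
        # advance the event clock up to and including this tick
        while events and events[0][0] <= tick_s:
            now, _, kind, p = heapq.heappop(events)
            if kind == "arrival":
                present.add(p)
                if free_beds > 0:
                    free_beds -= 1
                    seat(p, now)
                else:
                    waiting[p.acuity].append(p)
            elif kind == "service_end":
                if p.admitted:
                    p.state = "boarding"
                    p.boarding_start_s = now
                    heapq.heappush(
                        events, (now + p.boarding_s, seq, "boarding_end", p)
                    )
                    seq += 1
                else:
                    depart(p)
                    seat_from_queue(now)
            else:  # boarding_end
                depart(p)
                seat_from_queue(now)

        counts = [0, 0, 0, 0]
        boarding = 0
        vent = 0
        longest_admit_wait_h = 0.0
        for p in present:
            counts[p.acuity] += 1
            if p.ventilated:
                vent += 1
            if p.state == "boarding":
                boarding += 1
                wait_h = (tick_s - p.boarding_start_s) / 3600.0
                longest_admit_wait_h = max(longest_admit_wait_h, wait_h)
        snapshots.append(
            EDSnapshot(
                timestamp=config.start + timedelta(seconds=tick_s),
                n_white=counts[0],
                n_green=counts[1],
                n_yellow=counts[2],
                n_red=counts[3],
                boarding=boarding,
                vent=vent,
                longest_admit_wait=longest_admit_wait_h,
                last_bed_time=last_bed_wait_h,
            )
        )

    return SnapshotSeries(
        snapshots=snapshots,
        hospital=hospital,
        start=config.start,
        cadence=config.cadence,
    )
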