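from datetime import datetime

import numpy as np
import pytest

from edcrowd import (
    EDSnapshot,
    HospitalConfig,
    SimulationConfig,
    score_series,
    simulate,
)


@pytest.fixture(scope="session")
def hospital():
    """Reference site: 40 ED beds, 4 physicians, 1072 accredited beds."""
    return HospitalConfig.default_site()


@pytest.fixture(scope="session")
def small_hospital():
    return HospitalConfig(ed_beds=5, physicians=2, hospital_beds=100)


@pytest.fixture
def worked_snapshot():
    """Mixed-acuity snapshot used as the hand-arithmetic EDWIN example."""
    return EDSnapshot(
        timestamp=datetime(2016, 3, 14, 12, 0),
        n_white=2, n_green=10, n_yellow=5, n_red=1,
        boarding=0, vent=0, longest_admit_wait=0.0, last_bed_time=0.0,
    )


@pytest.fixture
def full_snapshot():
    """Fully occupied ED with boarding/vent/wait terms (NEDOCS example)."""
    return EDSnapshot(
        timestamp=datetime(2016, 3, 14, 12, 0),
        n_white=0, n_green=20, n_yellow=15, n_red=5,
        boarding=10, vent=1, longest_admit_wait=4.0, last_bed_time=1.0,
    )


@pytest.fixture(scope="session")
def week_series(hospital):
    """One simulated default week (the study's observation design)."""
    return simulate(SimulationConfig(days=7, seed=1), hospital)


@pytest.fixture(scope="session")
def week_scored(week_series, hospital):
    return score_series(week_series, hospital)


def random_snapshot(rng: np.random.Generator, max_count: int = 60) -> EDSnapshot:
    """A random but invariant-respecting snapshot for oracle sweeps."""
    counts = rng.integers(0, max_count // 4, size=4)
    total = int(counts.sum())
    return EDSnapshot(
        timestamp=datetime(2016, 3, 14) ,
        n_white=int(counts[0]), n_green=int(counts[1]),
        n_yellow=int(counts[2]), n_red=int(counts[3]),
        boarding=int(rng.integers(0, total + 1)),
        vent=int(rng.integers(0, total + 1)),
        longest_admit_wait=float(rng.uniform(0, 12)),
        last_bed_time=float(rng.uniform(0, 4)),
    )
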