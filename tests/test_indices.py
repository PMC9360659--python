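"""Index arithmetic, classification bands and the capacity-table sums."""

import math
from datetime import datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edcrowd import (
    EDSnapshot,
    EdwinLabel,
    HospitalConfig,
    NedocsLabel,
    classify_edwin,
    classify_nedocs,
    compute_edwin,
    compute_nedocs,
    total_accredited_beds,
)
from edcrowd.indices import (
    FLAG_DENOMINATOR_NONPOSITIVE,
    FLAG_NEGATIVE_SCORE,
)

from conftest import random_snapshot

TS = datetime(2016, 3, 14, 12, 0)


def snap(w=0, g=0, y=0, r=0, boarding=0, vent=0, admit_wait=0.0, lbt=0.0):
    return EDSnapshot(TS, w, g, y, r, boarding, vent, admit_wait, lbt)


class TestEdwin:
    def test_worked_example_hand_arithmetic(self, worked_snapshot, hospital):
        # numerator 1*2 + 2*10 + 3*5 + 4*1 = 41; denominator 4*(40-18) = 88
        iv = compute_edwin(worked_snapshot, hospital)
        assert iv.valid
        assert iv.value == pytest.approx(41 / 88, abs=1e-12)
        assert iv.label is EdwinLabel.ACTIVE_MANAGEABLE

    def test_empty_ed_scores_zero(self, hospital):
        iv = compute_edwin(snap(), hospital)
        assert iv.value == 0.0
        assert iv.valid
        assert iv.label is EdwinLabel.ACTIVE_MANAGEABLE

    def test_saturated_denominator_invalid_and_crowded(self, hospital):
        # as many patients as treatment beds: denominator exactly zero
        iv = compute_edwin(snap(g=40), hospital)
        assert not iv.valid
        assert FLAG_DENOMINATOR_NONPOSITIVE in iv.flags
        assert math.isnan(iv.value)
        assert iv.label is EdwinLabel.CROWDED

    def test_oversaturated_keeps_raw_negative_ratio(self, hospital):
        iv = compute_edwin(snap(g=50), hospital)
        assert not iv.valid
        assert iv.value == pytest.approx(100 / (4 * -10))
        assert iv.label is EdwinLabel.CROWDED

    def test_upgrading_acuity_increases_score(self, hospital):
        # moving one patient green -> red raises the numerator, B_A fixed
        lo = compute_edwin(snap(g=10, y=5), hospital).value
        hi = compute_edwin(snap(g=9, y=5, r=1), hospital).value
        assert hi > lo

    @settings(max_examples=200, derandomize=True)
    @given(
        counts=st.tuples(*[st.integers(0, 9)] * 4),
        upgrade=st.integers(0, 2),
    )
    def test_acuity_upgrade_monotone_property(self, counts, upgrade):
        """Upgrading any patient's triage code strictly increases EDWIN."""
        h = HospitalConfig(ed_beds=40, physicians=4, hospital_beds=1072)
        if counts[upgrade] == 0:
            counts = list(counts)
            counts[upgrade] = 1
        base = list(counts)
        upgraded = list(counts)
        upgraded[upgrade] -= 1
        upgraded[upgrade + 1] += 1
        lo = compute_edwin(snap(*base), h)
        hi = compute_edwin(snap(*upgraded), h)
        assert lo.valid and hi.valid
        assert hi.value > lo.value


class TestNedocs:
    def test_worked_example_hand_arithmetic(self, full_snapshot, hospital):
        # -20 + 85.8*(40/40) + 600*(10/1072) + 13.4*1 + 0.93*4 + 5.64*1
        expected = -20 + 85.8 + 600 * 10 / 1072 + 13.4 + 0.93 * 4 + 5.64
        iv = compute_nedocs(full_snapshot, hospital)
        assert iv.value == pytest.approx(expected, abs=1e-12)
        assert iv.value == pytest.approx(94.157, abs=1e-3)
        assert iv.label is NedocsLabel.BUSY

    def test_empty_system_scores_minus_twenty(self, hospital):
        iv = compute_nedocs(snap(), hospital)
        assert iv.value == -20.0
        assert FLAG_NEGATIVE_SCORE in iv.flags
        assert iv.valid  # negative scores are kept raw, not clamped
        assert iv.label is NedocsLabel.NORMAL

    def test_literal_variant_differs_only_in_first_term(
        self, full_snapshot, hospital
    ):
        std = compute_nedocs(full_snapshot, hospital, variant="standard")
        lit = compute_nedocs(full_snapshot, hospital, variant="literal")
        # standard first term: -20 + 85.8*1; literal: -20*85.8*1
        assert std.value - (-20 + 85.8) == pytest.approx(
            lit.value - (-20 * 85.8), abs=1e-9
        )

    def test_unknown_variant_rejected(self, full_snapshot, hospital):
        with pytest.raises(ValueError, match="variant"):
            compute_nedocs(full_snapshot, hospital, variant="weiss2006")

    @settings(max_examples=100, derandomize=True)
    @given(
        field=st.sampled_from(
            ["patients", "boarding", "vent", "longest_admit_wait",
             "last_bed_time"]
        ),
        seed=st.integers(0, 10_000),
    )
    def test_monotone_in_every_component(self, field, seed):
        """Standard NEDOCS never decreases when any input grows."""
        h = HospitalConfig(ed_beds=40, physicians=4, hospital_beds=1072)
        rng = np.random.default_rng(seed)
        s = random_snapshot(rng)
        kw = dict(
            w=s.n_white, g=s.n_green, y=s.n_yellow, r=s.n_red,
            boarding=s.boarding, vent=s.vent,
            admit_wait=s.longest_admit_wait, lbt=s.last_bed_time,
        )
        lo = compute_nedocs(snap(**kw), h).value
        if field == "patients":
            kw["g"] += 1
        elif field == "boarding":
            kw["g"] += 1  # keep boarding <= patients present
            kw["boarding"] += 1
        elif field == "vent":
            kw["g"] += 1
            kw["vent"] += 1
        elif field == "longest_admit_wait":
            kw["admit_wait"] += 1.0
        else:
            kw["lbt"] += 1.0
        hi = compute_nedocs(snap(**kw), h).value
        assert hi >= lo


class TestClassification:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.0, EdwinLabel.ACTIVE_MANAGEABLE),
            (1.0, EdwinLabel.ACTIVE_MANAGEABLE),
            (1.4999, EdwinLabel.ACTIVE_MANAGEABLE),
            (1.5, EdwinLabel.BUSY),       # "between 1.5 and 2" is inclusive
            (1.75, EdwinLabel.BUSY),
            (2.0, EdwinLabel.BUSY),
            (2.01, EdwinLabel.CROWDED),
            (10.0, EdwinLabel.CROWDED),
        ],
    )
    def test_edwin_bands(self, value, label):
        assert classify_edwin(value) is label

    def test_edwin_invalid_maps_to_crowded(self):
        assert classify_edwin(-3.0, valid=False) is EdwinLabel.CROWDED
        assert classify_edwin(0.5, valid=False) is EdwinLabel.CROWDED

    @pytest.mark.parametrize(
        "value,label",
        [
            (-20.0, NedocsLabel.NORMAL),
            (0.0, NedocsLabel.NORMAL),
            (25.0, NedocsLabel.NORMAL),
            (49.999, NedocsLabel.NORMAL),
            (50.0, NedocsLabel.BUSY),       # left-closed at 50
            (100.0, NedocsLabel.BUSY),
            (101.0, NedocsLabel.OVERCROWDED),
            (140.0, NedocsLabel.OVERCROWDED),
            (141.0, NedocsLabel.SEVERE_OVERCROWDING),
            (160.0, NedocsLabel.SEVERE_OVERCROWDING),
            (180.0, NedocsLabel.SEVERE_OVERCROWDING),
            (180.001, NedocsLabel.DISASTER),
            (500.0, NedocsLabel.DISASTER),
        ],
    )
    def test_nedocs_bands(self, value, label):
        assert classify_nedocs(value) is label

    @settings(max_examples=300, derandomize=True)
    @given(st.floats(-2000, 2000, allow_nan=False))
    def test_exhaustive_and_severity_monotone(self, v):
        """Every real maps to exactly one label; severity tracks the value."""
        e = classify_edwin(v)
        n = classify_nedocs(v)
        assert isinstance(e, EdwinLabel) and isinstance(n, NedocsLabel)
        assert classify_edwin(v + 0.5) >= e
        assert classify_nedocs(v + 25.0) >= n


class TestCapacityTable:
    def test_shipped_census_totals(self, hospital):
        day, hosp, grand = total_accredited_beds(hospital.capacity_table)
        assert (day, hosp, grand) == (122, 950, 1072)

    def test_empty_table(self):
        empty = pd.DataFrame(
            columns=["department", "day_hospital_beds", "hospitalization_beds"]
        )
        assert total_accredited_beds(empty) == (0, 0, 0)

    def test_two_row_hand_sum(self):
        t = pd.DataFrame(
            {
                "department": ["a", "b"],
                "day_hospital_beds": [2, 8],
                "hospitalization_beds": [24, 139],
            }
        )
        assert total_accredited_beds(t) == (10, 163, 173)

    @pytest.mark.parametrize("bad", [-1, 2.5])
    def test_rejects_negative_or_fractional_beds(self, bad):
        t = pd.DataFrame(
            {
                "department": ["a"],
                "day_hospital_beds": [bad],
                "hospitalization_beds": [3],
            }
        )
        with pytest.raises(ValueError):
            total_accredited_beds(t)

    def test_hospital_config_cross_checks_grand_total(self, hospital):
        with pytest.raises(ValueError, match="grand total"):
            HospitalConfig(
                ed_beds=40, physicians=4, hospital_beds=999,
                capacity_table=hospital.capacity_table,
            )


class TestSnapshotInvariants:
    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError, match="n_green"):
            EDSnapshot(TS, 0, -1, 0, 0, 0, 0, 0.0, 0.0)

    def test_rejects_boarding_above_present(self):
        with pytest.raises(ValueError, match="boarding"):
            EDSnapshot(TS, 1, 0, 0, 0, 2, 0, 0.0, 0.0)

    def test_rejects_nonfinite_waits(self):
        with pytest.raises(ValueError, match="longest_admit_wait"):
            EDSnapshot(TS, 1, 0, 0, 0, 0, 0, float("inf"), 0.0)

    def test_total_is_sum_of_codes(self):
        s = EDSnapshot(TS, 1, 2, 3, 4, 0, 0, 0.0, 0.0)
        assert s.total_patients == 10
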