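# Methods

## Scope and data model

The package scores timestamped ED status snapshots with the EDWIN and
NEDOCS crowding indices, classifies every observation into the scales'
crowding bands, aggregates band shares over calendar groupings, and
quantifies the association between the two indices with Kendall's τ-b.
Because real ED information-system feeds are confidential, a synthetic
patient-flow simulator generates snapshot streams with the structure the
analysis assumes; everything downstream treats simulated and ingested CSV
data identically.

A snapshot is an instantaneous census: patients present per triage colour
code (white/green/yellow/red, the Italian four-level acuity scale),
boarding count, ventilated count, the longest current boarding wait and
the door-to-bed time of the last patient seated.  The hospital
configuration carries the static capacities the formulas need: ED
treatment beds `B_T` (default 40), attending physicians `N_a` (default 4)
and accredited hospital beds `H_beds` (default 1072, the grand total of
the packaged 29-department census: 122 day-hospital + 950 hospitalization
beds).

## Index conventions

**EDWIN saturation.**  `Σ nᵢtᵢ / (Nₐ(B_T − B_A))` is undefined at
`B_A = B_T` and negative beyond it.  Such ticks are flagged
`denominator_nonpositive`, marked invalid, and *classified* as crowded —
a department at or over physical bed capacity is crowded regardless of the
ratio's sign.  The raw signed ratio is preserved for a negative
denominator (NaN for exactly zero) so that a sensitivity analysis can
include it; the inter-index comparison drops saturated ticks by default
(`policy="drop_saturated"`), with `include_raw` as the alternative, and
reports how many were dropped.

**NEDOCS variant.**  The default is the standard additive Weiss form
(−20 constant plus an 85.8 occupancy coefficient).  Some sources print the
first term multiplicatively (−20·85.8·occupancy), which yields scores
around −1700 for a full ED — outside every published band, so it cannot
be the operational formula; it is nevertheless implemented verbatim behind
`variant="literal"` so such sources can be audited.  Negative scores are
kept raw (flagged `negative_score`, banded normal), never clamped, so
correlations see the true values.

**Band boundaries.**  Published band edges overlap at 50/101/141/180 and
1.5/2.  The package fixes one convention and applies it everywhere:
NEDOCS bands are left-closed/right-open at 50, 101 and 141, severe
overcrowding covers [141, 180], disaster is strictly above 180; EDWIN's
busy band is inclusive at both ends ([1.5, 2]).  Both label scales are
totally ordered by severity, and classification is exhaustive over the
reals.

**Units.**  All wait-time inputs are hours (the stated unit of the longest
admit wait; the door-to-bed time has no published unit and is taken in
hours for coherence — its 5.64 coefficient then acts per hour).
Timestamps are timezone-naive local clock time, since the diurnal analyses
are local-clock based.

**TP vs B_A.**  Both formulas need "patients present"; one field serves
both so the two indices can never be fed inconsistent censuses.

## Statistical comparison

Each margin is tested with Shapiro–Wilk (scipy's Royston implementation;
3 ≤ n ≤ 5000, constant input rejected); `normal` means p ≥ α with α = 0.05
by default.  Kendall's τ is computed and reported regardless of the
normality outcome — the gate result is recorded as justification rather
than switching estimators, and a Pearson r is included as supplementary
output.  The τ-b (tie-corrected) variant is used because 15-minute index
series tie heavily.  P-values use the exact permutation distribution for
n ≤ 10 without ties and the normal approximation otherwise.  Strength
bands on |τ|: ≤ 0.10 very weak, < 0.40 weak, < 0.70 moderate, ≥ 0.70
strong — the 0.10 boundary goes to the lower band, 0.40 and 0.70 to the
upper, closing the half-open published ranges.  The test suite checks τ-b
exactly against an independent O(n²) concordant/discordant/tie count and
calibrates the test's type-I error at 5% ± 1% under an independence null.

## The simulator

Arrivals are a nonhomogeneous Poisson process realised by thinning against
the maximum rate; the intensity at time t is
`base_arrival_rate × diurnal[hour] × weekday[weekday]`.  Each arrival
draws acuity from the configured mix, a treatment duration from an
exponential law (lognormal optional, mean-matched) with the acuity's mean,
an admission indicator, an exponential boarding duration if admitted, and
a ventilation flag fixed at arrival (a patient's ventilation status does
not flicker between snapshots).  Patients wait in a virtual waiting room
while all treatment beds are occupied; the queue is acuity-priority (red
first), FIFO within acuity, matching triage practice.  Admitted patients
keep their treatment bed while boarding — that is precisely the mechanism
by which boarding causes crowding.  All draws flow from a single seeded
`numpy` generator, so one integer seed reproduces a run bit for bit.

### Default scenario

The defaults emulate a large urban ED and are synthetic stand-ins, not
measured values:

| parameter | default | rationale |
|---|---|---|
| base arrival rate | 12.5 /h | ≈ 300 arrivals/day after profile shaping |
| diurnal profile | 0.45 overnight, ramp 06–09, 1.30 from 09:00 to midnight | morning-to-midnight peak |
| weekday profile | Mon–Fri 1.10–1.15, Sat 0.80, Sun 0.75 | midweek above weekend |
| acuity mix | 5% white, 55% green, 32% yellow, 8% red | green-dominant triage case mix |
| mean LOS (h) | 0.5 / 1.1 / 1.9 / 2.6 by acuity | calibrated so the reference site (40 beds, 4 physicians) runs mostly manageable-to-busy with occasional saturation (~1% of ticks), the regime the indices are designed to discriminate |
| admission prob. | 1% / 5% / 25% / 70% by acuity | severity-dependent admission |
| mean boarding | 1.5 h | occasional multi-patient boarding |
| ventilation prob. | 2% | rare ventilated patients |

With these defaults a simulated week shows the expected structure: midweek
daytime census around 25–35 of 40 beds, quiet weekends, EDWIN mostly below
1.5 with a crowded tail, NEDOCS mostly normal-to-busy.

### What the simulator does and does not emulate

It reproduces the *statistical shape* the analysis needs — diurnal and
weekly load cycles, acuity mix, boarding-driven bed blocking, waiting-room
overflow, occasional saturation — not any real department's magnitudes.
Real feeds have gaps, re-triage (colour upgrades mid-stay), ambulance
batching, staff-roster discontinuities and long-tailed boarding during bed
crises; none are modelled.  Severe-overcrowding and disaster NEDOCS bands
are reached only during occupancy surges well above bed capacity, which
the default load produces rarely or not at all in a single week.
Consequently, passing tests demonstrate that the *measurement machinery*
is correct and that the pipeline's qualitative contrasts (midweek >
weekend, peak window > overnight, positive inter-index association) emerge
from load structure — they do not certify any particular real-world band
percentage or correlation magnitude.  On synthetic data both indices are
driven by the same occupancy process, so their τ is strong; a real
department, where wait times, boarding and census decouple, can show much
weaker association.

## Numerical and design choices

- Snapshot grids: a series has exactly `days × 86400 / cadence` ticks at
  `start + k·cadence`; the cadence must divide 86400 s (default 900 s).
- Event ties at a tick boundary are processed before the snapshot is
  taken (departures at exactly the tick are not counted present).
- CSV round-trips are lossless: floats are written `%.17g` and parsed
  with round-trip precision; readers validate every row against the
  snapshot invariants and name the offending line.  Duplicate timestamps
  are errors; out-of-order rows are sorted with a warning (rejected under
  `--strict`); gaps are permitted and logged, never imputed — denominators
  count observed ticks.
- Aggregation always uses the classifier bands, so reported percentages
  are internally consistent by construction; per-group percentages sum to
  100 over band columns (plus the saturated column for EDWIN).
- Weekend means Saturday and Sunday.
- Window boundaries for time-of-day summaries are user parameters
  (defaults in the analysis scripts: 09–24 vs 00–09).

## Problem sizes

The test suite and acceptance script use one-to-seven simulated days per
scenario (672 ticks per week, ≈ 2,000 patients), 1,000-snapshot oracle
sweeps, 200 random series for the τ oracle, and 10,000 replicates of
n = 50 for null calibration; the whole suite runs in well under a minute.

## Known limitations

- The waiting-room discipline ignores treatment preemption and
  fast-track streams.
- Boarding durations are independent of hospital-ward occupancy (no
  feedback from the 1072-bed census to boarding times).
- The Shapiro–Wilk gate is capped at n = 5000 by the underlying
  algorithm; longer series must be windowed first.
- `IndexSeries` read from a scored CSV infers cadence from the first two
  timestamps.
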