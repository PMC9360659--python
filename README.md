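# edcrowd

Measurement and comparison of emergency-department (ED) crowding with the
two most widely used multidimensional indices — **EDWIN** (Emergency
Department Work Index) and **NEDOCS** (National Emergency Department
Overcrowding Scale) — over streams of 15-minute ED status snapshots, plus a
synthetic ED patient-flow simulator so the whole analysis runs end-to-end
on generated data.  It is written for hospital quality/operations analysts
and health-services researchers who want to score, band and compare
crowding measurements from an ED information system (or study the indices'
behaviour on simulated load).

## The indices

Each snapshot records the ED census per Italian triage colour code (white,
green, yellow, red), the boarding count (admitted patients held in the ED
awaiting an inpatient bed), ventilated patients and two wait times.

**EDWIN** is acuity-weighted load per physician per free treatment bed:

```
EDWIN = Σᵢ nᵢ·tᵢ / (Nₐ · (B_T − B_A))
```

with `nᵢ` patients in triage category `i`, weights `tᵢ` = 1 (white) … 4
(red), `Nₐ` attending physicians, `B_T` treatment beds and `B_A` patients
present.  Bands: < 1.5 active but manageable, 1.5–2 busy, > 2 crowded.
When `B_A ≥ B_T` the denominator is non-positive; such scores are flagged
invalid (saturated) and classified as crowded.

**NEDOCS** (standard additive Weiss form, the default) is

```
NEDOCS = −20 + 85.8·(TP/ED_beds) + 600·(Brdg/H_beds)
         + 13.4·Vent + 0.93·LongAdmt + 5.64·LBT
```

with `TP` patients present, `ED_beds` treatment beds, `Brdg` boarders,
`H_beds` accredited hospital beds, `Vent` ventilated patients, `LongAdmt`
the longest current boarding wait (hours) and `LBT` the door-to-bed time of
the last patient seated (hours).  Bands: [0, 50) normal, [50, 101) busy,
[101, 141) overcrowded, [141, 180] severe overcrowding, > 180 disaster.
A literal variant with a multiplicative first term (−20·85.8·occupancy) is
available behind `variant="literal"` / `--nedocs-form literal` for auditing
sources that print the formula that way.

The two indices are compared by pairing their values tick by tick, testing
each margin for normality (Shapiro–Wilk), and computing **Kendall's τ-b**
(tie-corrected) with |τ| strength bands: < 0.10 very weak, < 0.40 weak,
< 0.70 moderate, above that strong.

## Worked example

The default reference site has 40 ED treatment beds, 4 attending
physicians, and 1072 accredited hospital beds (the packaged per-department
census sums to 122 day-hospital + 950 hospitalization beds).

```python
from datetime import datetime
from edcrowd import EDSnapshot, HospitalConfig, compute_edwin, compute_nedocs

h = HospitalConfig.default_site()
s = EDSnapshot(datetime(2016, 3, 14, 12), n_white=2, n_green=10, n_yellow=5,
               n_red=1, boarding=0, vent=0, longest_admit_wait=0.0,
               last_bed_time=0.0)
compute_edwin(s, h).value     # 0.4659  = 41 / (4 * (40 - 18))  -> active/manageable

full = EDSnapshot(datetime(2016, 3, 14, 12), 0, 20, 15, 5, boarding=10,
                  vent=1, longest_admit_wait=4.0, last_bed_time=1.0)
compute_nedocs(full, h).value # 94.157  -> busy
```

The shell pipeline runs the same computation end to end on simulated data:

```
edcrowd simulate --days 7 --seed 1 --out snapshots.csv
edcrowd score snapshots.csv --out scored.csv
edcrowd report scored.csv --grouping weekpart
edcrowd compare scored.csv --out comparison.json
```

which prints, for seed 1 (abridged):

```
EDWIN band percentages by weekpart:
          active_manageable  busy  crowded  saturated
weekday               63.75  7.92    27.50       0.83
weekend               96.35  2.08     1.56       0.00
Kendall tau-b = 0.7562 (p = 2.8e-187, n = 668): strong positive correlation
```

i.e. the simulated department is far busier midweek than at the weekend,
0.83% of weekday ticks saturate the EDWIN denominator, and the two indices
rank crowding consistently (both are driven by occupancy, so on synthetic
load their association is strong).  The numbered scripts under `analysis/`
(`01_simulate.py` … `04_compare.py`) run the same sequence as a narrative
analysis and write their tables under `results/`.

Snapshot CSV schema (header mandatory; wait times in hours; timestamps
ISO-8601, timezone-naive local clock):

```
timestamp,n_white,n_green,n_yellow,n_red,boarding,vent,longest_admit_wait_h,last_bed_time_h
```

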