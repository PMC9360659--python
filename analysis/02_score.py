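#!/usr/bin/env python
"""Score the snapshot stream with EDWIN and NEDOCS.

Reads results/snapshots.csv, applies both indices to every tick (standard
additive NEDOCS form) and writes the scored stream to results/scored.csv.
Reports how often the EDWIN denominator saturated (patients >= beds).
"""

import argparse
from pathlib import Path

from edcrowd import HospitalConfig, score_series
from edcrowd.io import read_snapshots, write_scored

parser = argparse.ArgumentParser()
parser.add_argument("--results-dir", default="results")
args = parser.parse_args()

out = Path(args.results_dir)
hospital = HospitalConfig.default_site()
series = read_snapshots(str(out / "snapshots.csv"), hospital=hospital)
iseries = score_series(series, hospital)
write_scored(iseries, series, str(out / "scored.csv"))

d = iseries.data
n_sat = int((~d["edwin_valid"]).sum())
print(f"scored {len(d)} ticks")
print(f"EDWIN: mean {d.loc[d.edwin_valid, 'edwin_value'].mean():.3f} "
      f"(valid ticks), {n_sat} saturated ({100 * n_sat / len(d):.1f}%)")
print(f"NEDOCS: mean {d['nedocs_value'].mean():.1f}, "
      f"max {d['nedocs_value'].max():.1f}")
print(f"wrote {out / 'scored.csv'}")
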