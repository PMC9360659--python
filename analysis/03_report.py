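#!/usr/bin/env python
"""Aggregate scored ticks into crowding-band reports.

Produces the per-day, weekday/weekend and hour-of-day band-percentage
tables for both indices, plus the peak-window (09-24) versus overnight
(00-09) contrast, and writes them as Markdown under results/.
"""

import argparse
from pathlib import Path

from edcrowd import band_proportions, window_summary
from edcrowd.io import read_scored

parser = argparse.ArgumentParser()
parser.add_argument("--results-dir", default="results")
args = parser.parse_args()

out = Path(args.results_dir)
iseries = read_scored(str(out / "scored.csv"))

lines = []
for index_name in ("EDWIN", "NEDOCS"):
    for grouping in ("per_day", "weekpart", "hour_window"):
        tab = band_proportions(iseries, index_name, grouping).round(2)
        lines += [f"## {index_name} band % by {grouping}", "", tab.to_markdown(), ""]
        if grouping != "hour_window":
            print(f"{index_name} by {grouping}:")
            print(tab.to_string(), "\n")

peak = window_summary(iseries, 9, 24)
night = window_summary(iseries, 0, 9)
contrast = (
    f"peak window 09-24: mean NEDOCS {peak.nedocs_mean:.1f}, "
    f"mean EDWIN {peak.edwin_mean:.2f} ({peak.n_ticks} ticks)\n"
    f"overnight 00-09:   mean NEDOCS {night.nedocs_mean:.1f}, "
    f"mean EDWIN {night.edwin_mean:.2f} ({night.n_ticks} ticks)"
)
print(contrast)
lines += ["## Peak vs overnight windows", "", "```", contrast, "```", ""]

(out / "band_report.md").write_text("\n".join(lines))
print(f"wrote {out / 'band_report.md'}")
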