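#!/usr/bin/env python
"""Inter-index comparison: normality gate, Kendall tau-b, strength band.

Pairs the EDWIN/NEDOCS values tick by tick (dropping saturated-EDWIN
ticks), runs Shapiro-Wilk on each margin, computes Kendall's tau-b with
its significance, and writes the comparison report and the scatter pairs
under results/.
"""

import argparse
from pathlib import Path

from edcrowd import compare_indices
from edcrowd.io import read_scored

parser = argparse.ArgumentParser()
parser.add_argument("--results-dir", default="results")
parser.add_argument("--alpha", type=float, default=0.05)
args = parser.parse_args()

out = Path(args.results_dir)
iseries = read_scored(str(out / "scored.csv"))
report = compare_indices(iseries, alpha=args.alpha)
report.to_json(str(out / "comparison.json"))
report.scatter.to_csv(out / "scatter.csv", index=False)

e, n, c = report.edwin_normality, report.nedocs_normality, report.correlation
print(f"paired ticks: {c.n_pairs} ({report.n_dropped_saturated} saturated dropped)")
print(f"Shapiro-Wilk: EDWIN W={e.statistic:.4f} p={e.p_value:.3g}; "
      f"NEDOCS W={n.statistic:.4f} p={n.p_value:.3g}"
      f" -> {'non-normal margin(s), rank correlation' if not (e.normal and n.normal) else 'both margins normal'}")
print(f"Kendall tau-b = {c.tau:.4f} (p = {c.p_value:.3g}): "
      f"{c.strength} {c.sign} correlation")
print(f"least-squares: nedocs = {report.slope:.2f}*edwin + {report.intercept:.2f}; "
      f"Pearson r = {report.pearson_r:.3f}")
print(f"wrote {out / 'comparison.json'} and {out / 'scatter.csv'}")
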