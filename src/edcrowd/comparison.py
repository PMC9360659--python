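"""Inter-index statistical comparison: normality gate, Kendall τ-b, banding.

The workflow mirrors standard practice for comparing two crowding indices
measured on the same snapshot grid: check each margin for normality with
the Shapiro–Wilk test, then quantify association with Kendall's rank
correlation.  The tie-corrected τ-b variant is used because index values at
a 15-minute cadence tie frequently.  Kendall's τ is reported regardless of
the normality outcome (the Shapiro–Wilk results are recorded as the
justification); a Pearson coefficient is included as supplementary output.

Strength bands for |τ|: very weak below 0.10, weak up to 0.40, moderate up
to 0.70, strong above.  The boundary 0.10 goes to the lower band; 0.40 and
0.70 go to the upper band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .timeseries import IndexSeries, band_proportions


@dataclass(frozen=True)
class NormalityResult:
    statistic: float  # Shapiro-Wilk W
    p_value: float
    normal: bool  # decision at alpha
    alpha: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    tau: float
    p_value: float
    n_pairs: int
    strength: str  # very_weak | weak | moderate | strong
    sign: str  # positive | negative | zero


@dataclass(frozen=True)
class ComparisonReport:
    edwin_normality: NormalityResult
    nedocs_normality: NormalityResult
    correlation: CorrelationResult
    pearson_r: float
    n_total: int
    n_dropped_saturated: int
    policy: str
    edwin_band_pct: dict
    nedocs_band_pct: dict
    scatter: pd.DataFrame  # paired (edwin, nedocs) values
    slope: float  # least-squares nedocs ~ edwin
    intercept: float

    def to_dict(self) -> dict:
        d = {
            "normality": {
                "edwin": vars(self.edwin_normality).copy(),
                "nedocs": vars(self.nedocs_normality).copy(),
            },
            "correlation": vars(self.correlation).copy(),
            "pearson_r": self.pearson_r,
            "n_total": self.n_total,
            "n_dropped_saturated": self.n_dropped_saturated,
            "policy": self.policy,
            "edwin_band_pct": self.edwin_band_pct,
            "nedocs_band_pct": self.nedocs_band_pct,
            "regression": {"slope": self.slope, "intercept": self.intercept},
        }
        return d

    def to_json(self, path: Optional[str] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def shapiro_wilk(values: Sequence[float], alpha: float = 0.05) -> NormalityResult:
    """Shapiro–Wilk normality test; ``normal`` is ``p >= alpha``."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"Shapiro-Wilk needs n >= 3, got {n}")
    if n > 5000:
        raise ValueError(f"Shapiro-Wilk supports n <= 5000, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for constant input")
    w, p = stats.shapiro(x)
    return NormalityResult(
        statistic=float(w), p_value=float(p), normal=bool(p >= alpha),
        alpha=alpha, n=n,
    )


def strength_label(tau: float) -> str:
    """Band |τ|: very_weak (≤0.10), weak (<0.40), moderate (<0.70), strong."""
    a = abs(tau)
    if a > 1:
        raise ValueError(f"|tau| must be <= 1, got {tau}")
    if a <= 0.10:
        return "very_weak"
    if a < 0.40:
        return "weak"
    if a < 0.70:
        return "moderate"
    return "strong"


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Kendall's τ-b with tie correction.

    The p-value uses the normal approximation for n > 10 and exact
    enumeration of the permutation distribution for n <= 10 (ties force the
    approximation: the exact null distribution assumes distinct ranks).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    n = len(x)
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("tau undefined: one margin is entirely tied")
    has_ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    method = "exact" if (n <= 10 and not has_ties) else "asymptotic"
    res = stats.kendalltau(x, y, variant="b", method=method)
    tau = float(res.statistic)
    if tau > 0:
        sign = "positive"
    elif tau < 0:
        sign = "negative"
    else:
        sign = "zero"
    return CorrelationResult(
        tau=tau, p_value=float(res.pvalue), n_pairs=n,
        strength=strength_label(tau), sign=sign,
    )


def compare_indices(
    iseries: IndexSeries,
    alpha: float = 0.05,
    policy: str = "drop_saturated",
) -> ComparisonReport:
    """Pair the two index series and run the full comparison.

    ``policy`` controls saturated-EDWIN ticks (denominator <= 0):
    ``drop_saturated`` (default) excludes them from the paired analysis;
    ``include_raw`` keeps the raw signed ratios (NaN ticks from an exactly
    zero denominator are always dropped).
    """
    if policy not in ("drop_saturated", "include_raw"):
        raise ValueError(f"unknown policy {policy!r}")
    df = iseries.data
    n_total = len(df)
    if policy == "drop_saturated":
        keep = df["edwin_valid"].to_numpy(dtype=bool)
    else:
        keep = np.isfinite(df["edwin_value"].to_numpy(dtype=float))
    paired = df.loc[keep, ["edwin_value", "nedocs_value"]].rename(
        columns={"edwin_value": "edwin", "nedocs_value": "nedocs"}
    )
    n_pairs = len(paired)
    if n_pairs < 3:
        raise ValueError(
            f"insufficient data: {n_pairs} valid pairs (need >= 3)"
        )
    x = paired["edwin"].to_numpy()
    y = paired["nedocs"].to_numpy()

    edwin_norm = shapiro_wilk(x, alpha=alpha)
    nedocs_norm = shapiro_wilk(y, alpha=alpha)
    corr = kendall_tau(x, y)
    pearson_r = float(stats.pearsonr(x, y).statistic)
    slope, intercept = np.polyfit(x, y, 1)

    e_tab = band_proportions(iseries, "EDWIN", "per_day")
    n_tab = band_proportions(iseries, "NEDOCS", "per_day")
    return ComparisonReport(
        edwin_normality=edwin_norm,
        nedocs_normality=nedocs_norm,
        correlation=corr,
        pearson_r=pearson_r,
        n_total=n_total,
        n_dropped_saturated=n_total - n_pairs,
        policy=policy,
        edwin_band_pct={str(k): dict(v) for k, v in e_tab.iterrows()},
        nedocs_band_pct={str(k): dict(v) for k, v in n_tab.iterrows()},
        scatter=paired.reset_index(drop=True),
        slope=float(slope),
        intercept=float(intercept),
    )
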