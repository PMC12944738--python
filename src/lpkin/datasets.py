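"""Bundled worked-example data: published two-method agreement summaries.

A markerless vision system and a cable linear-position transducer were
compared on 247 landmine-press trials across four loads (20-35 kg).  The
published per-group summaries — Bland–Altman bias and 95% limits of
agreement, Pearson r, paired-t p value, Cohen's d, and Deming slope and
intercept, printed to two decimals — are reproduced here as a worked
example for the agreement module.

The bias/LoA columns fully determine the paired Cohen's d convention
(mean of differences over their SD), since ``sd_diff`` can be recovered as
``(loa_upper - loa_lower) / (2 * 1.96)``; cross-checking the recomputed d
against the printed d validates the implementation against the original
analysis without access to the raw trials.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_agreement_summaries", "N_PER_LOAD"]

#: Trial counts per load group in the comparison study.
N_PER_LOAD = {"all": 247, "20kg": 72, "25kg": 63, "30kg": 56, "35kg": 56}

# load, indicator, bias, loa_lower, loa_upper, r, p, cohens_d, slope, intercept
_ROWS = [
    ("all", "peak_velocity", 0.19, -0.25, 0.64, 0.91, 0.00, 0.86, 1.18, -0.15),
    ("all", "mean_velocity", 0.23, 0.02, 0.45, 0.86, 0.00, 2.10, 1.14, 0.05),
    ("all", "peak_power", 18.06, -312.52, 348.63, 0.86, 0.09, 0.11, 1.10, -59.38),
    ("all", "mean_power", -7.63, -116.18, 100.92, 0.90, 0.03, -0.14, 0.92, 26.20),
    ("20kg", "peak_velocity", 0.18, -0.29, 0.64, 0.92, 0.00, 0.74, 1.12, -0.08),
    ("20kg", "mean_velocity", 0.26, -0.03, 0.54, 0.91, 0.00, 1.78, 1.11, 0.11),
    ("20kg", "peak_power", 7.26, -294.99, 309.52, 0.88, 0.69, 0.05, 0.99, 16.02),
    ("20kg", "mean_power", -19.92, -143.92, 104.07, 0.90, 0.01, -0.32, 0.77, 62.91),
    ("25kg", "peak_velocity", 0.23, -0.27, 0.72, 0.87, 0.00, 0.90, 1.27, -0.35),
    ("25kg", "mean_velocity", 0.24, 0.02, 0.46, 0.91, 0.00, 2.16, 1.05, 0.18),
    ("25kg", "peak_power", 30.10, -285.51, 345.70, 0.83, 0.14, 0.19, 1.20, -133.39),
    ("25kg", "mean_power", -13.09, -116.78, 90.61, 0.89, 0.05, -0.25, 0.81, 66.51),
    ("30kg", "peak_velocity", 0.13, -0.17, 0.43, 0.93, 0.00, 0.87, 1.15, -0.14),
    ("30kg", "mean_velocity", 0.21, 0.05, 0.37, 0.94, 0.00, 2.54, 1.18, -0.01),
    ("30kg", "peak_power", -27.90, -309.70, 253.91, 0.83, 0.15, -0.19, 1.04, -55.85),
    ("30kg", "mean_power", -13.48, -117.57, 90.62, 0.87, 0.06, -0.25, 1.00, -13.79),
    ("35kg", "peak_velocity", 0.24, -0.21, 0.69, 0.90, 0.00, 1.04, 1.26, -0.23),
    ("35kg", "mean_velocity", 0.22, 0.07, 0.38, 0.95, 0.00, 2.78, 1.07, 0.13),
    ("35kg", "peak_power", 64.35, -337.25, 465.94, 0.85, 0.02, 0.31, 1.12, -38.47),
    ("35kg", "mean_power", 20.18, -56.30, 96.66, 0.94, 0.00, 0.52, 0.99, 24.26),
]


def load_agreement_summaries() -> pd.DataFrame:
    """Published per-group agreement summaries as a tidy DataFrame.

    Columns: ``load, indicator, n, bias, loa_lower, loa_upper, r, p,
    cohens_d, deming_slope, deming_intercept``.  Velocity rows are in m/s,
    power rows in W; all values as printed (two decimals).
    """
    frame = pd.DataFrame(
        _ROWS,
        columns=["load", "indicator", "bias", "loa_lower", "loa_upper",
                 "r", "p", "cohens_d", "deming_slope", "deming_intercept"],
    )
    frame.insert(2, "n", frame["load"].map(N_PER_LOAD))
    return frame
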