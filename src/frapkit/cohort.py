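"""Cohort summaries across conditions and cell-cycle phases.

Per-experiment half-times and mobile fractions are aggregated with the
boxplot convention used throughout the study (box bounds the
interquartile range divided by the median; whiskers extend at most
1.5 x IQR beyond the box) and compared with two-tailed, two-sample,
unequal-variance (Welch) t-tests. Quartiles use linear interpolation
between order statistics (numpy's default, R type 7). Cell-cycle phase
is an input label, never inferred; raw p-values are reported by default
with Holm correction available.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

PHASES = ("G1", "S", "G2", "unassigned")
RECORD_COLUMNS = ["experiment_id", "condition", "phase", "time_min", "t_half_ms", "f_m"]


@dataclass
class BoxSummary:
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray
    n: int


def summarize_group(values) -> BoxSummary:
    """Five-number boxplot summary with 1.5 x IQR whiskers.

    Whiskers sit on the most extreme data points within
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR]; points beyond are outliers.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty group")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=np.sort(values[(values < lo_fence) | (values > hi_fence)]),
        n=values.size,
    )


@dataclass
class WelchResult:
    statistic: float
    df: float
    p_value: float


def welch_statistic(mean_a, var_a, n_a, mean_b, var_b, n_b):
    """Vectorized Welch t statistic and Welch-Satterthwaite df."""
    sa, sb = var_a / n_a, var_b / n_b
    se2 = sa + sb
    t = (mean_a - mean_b) / np.sqrt(se2)
    df = se2**2 / (sa**2 / (n_a - 1) + sb**2 / (n_b - 1))
    return t, df


def welch_t_test(group_a, group_b) -> WelchResult:
    """Two-tailed, two-sample, unequal-variance t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if np.isclose(a.mean(), b.mean()):
            return WelchResult(0.0, float(len(a) + len(b) - 2), 1.0)
        log.warning("both groups have zero variance and different means")
        return WelchResult(np.inf, float(len(a) + len(b) - 2), 0.0)
    t, df = welch_statistic(a.mean(), va, len(a), b.mean(), vb, len(b))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(float(t), float(df), p)


def holm_correction(p_values: dict) -> dict:
    """Holm step-down adjustment of a dict of raw p-values."""
    items = sorted(p_values.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted = {}
    running = 0.0
    for rank, (key, p) in enumerate(items):
        running = max(running, (m - rank) * p)
        adjusted[key] = min(1.0, running)
    return adjusted


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records CSV missing columns: {sorted(missing)}")
    bad = set(df["phase"].dropna()) - set(PHASES)
    if bad:
        raise ValueError(f"unknown phase labels: {sorted(bad)}")
    if (df["t_half_ms"] <= 0).any():
        raise ValueError("t_half_ms must be positive")
    return df


@dataclass
class PhaseProfile:
    summaries: dict  # phase -> BoxSummary
    tests: dict  # (phase_a, phase_b) -> WelchResult
    scatter: pd.DataFrame  # t_half vs time since release, for plotting
    multiple_testing: str = "none"
    adjusted_p: dict | None = None


def phase_profile(records: pd.DataFrame, value: str = "t_half_ms", holm: bool = False):
    """Per-phase box summaries, pairwise Welch tests and a time-resolved
    scatter table.

    Phases with fewer than 2 records are summarized but excluded from
    tests (with a warning). No multiple-testing correction is applied by
    default; pass ``holm=True`` for Holm-adjusted p-values alongside.
    """
    if "phase" not in records.columns:
        raise ValueError("records need a 'phase' column")
    present = [p for p in PHASES if (records["phase"] == p).any()]
    summaries = {
        p: summarize_group(records.loc[records["phase"] == p, value]) for p in present
    }
    testable = []
    for p in present:
        if p == "unassigned":
            continue
        if summaries[p].n < 2:
            log.warning("phase %s has n < 2; excluded from tests", p)
            continue
        testable.append(p)
    tests = {}
    for pa, pb in itertools.combinations(testable, 2):
        tests[(pa, pb)] = welch_t_test(
            records.loc[records["phase"] == pa, value],
            records.loc[records["phase"] == pb, value],
        )
    scatter_cols = [c for c in ("time_min", value, "phase") if c in records.columns]
    scatter = records[scatter_cols].copy()
    adjusted = None
    if holm and tests:
        adjusted = holm_correction({k: v.p_value for k, v in tests.items()})
    return PhaseProfile(
        summaries=summaries,
        tests=tests,
        scatter=scatter,
        multiple_testing="holm" if holm else "none",
        adjusted_p=adjusted,
    )
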