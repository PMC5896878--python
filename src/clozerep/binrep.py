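"""Bin-averaged replication route: decile binning, within- then across-
participant grand averages per lab, per-channel Pearson correlations, lab
pooling, and Fisher-z confidence intervals.

The route mirrors the original averaging-based analysis: trials are sorted
into ten cloze bins (0-10, 11-20, ..., 91-100), averaged per participant
within bins, then across participants per laboratory.  Each laboratory
contributes at most ten (bin-average cloze, bin-average amplitude) points
per channel; the Pearson correlation over those points is the replication
statistic.  Pooling treats the laboratories as multiple observations of
each bin average (lab x bin rows are concatenated, not averaged).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "assign_bin",
    "grand_bin_averages",
    "correlate_bins",
    "corr_map",
    "pool_labs",
    "fisher_ci",
]


def assign_bin(cloze) -> np.ndarray:
    """Cloze decile bin index 1..10.

    Bin 1 covers cloze in [0, 10]; bin k >= 2 covers (10(k-1), 10k], i.e.
    the integer ranges 0-10, 11-20, ..., 91-100.  Accepts scalars or arrays;
    raises on cloze outside [0, 100].
    """
    arr = np.asarray(cloze, dtype=float)
    if np.any((arr < 0) | (arr > 100)) or np.any(~np.isfinite(arr)):
        raise ValueError("cloze values must lie in [0, 100]")
    bins = np.where(arr <= 10.0, 1, np.ceil(arr / 10.0)).astype(int)
    if bins.ndim == 0:
        return int(bins)
    return bins


def grand_bin_averages(
    table: pd.DataFrame,
    value_cols=("roi_n400",),
    group: str = "lab_id",
) -> pd.DataFrame:
    """Within- then across-participant bin averages per laboratory.

    Per participant: unweighted mean amplitude and mean cloze over the
    trials in each occupied bin.  Per lab: unweighted mean over the
    participants occupying the bin (a participant with 3 trials in a bin
    counts exactly as much as one with 30).  Empty (lab, bin) cells are
    absent rows, not zeros.

    Returns one row per (lab, bin) with ``mean_cloze``, one column per
    entry of ``value_cols``, ``n_participants`` and ``n_trials``.
    """
    if table.empty:
        raise ValueError("trial table is empty")
    value_cols = list(value_cols)
    work = table.copy()
    work["bin_index"] = assign_bin(work["cloze"].to_numpy())

    per_subj = (
        work.groupby([group, "subject_id", "bin_index"], observed=True)
        .agg(
            n_trials=("cloze", "size"),
            mean_cloze=("cloze", "mean"),
            **{c: (c, "mean") for c in value_cols},
        )
        .reset_index()
    )
    per_lab = (
        per_subj.groupby([group, "bin_index"], observed=True)
        .agg(
            mean_cloze=("mean_cloze", "mean"),
            **{c: (c, "mean") for c in value_cols},
            n_participants=("subject_id", "nunique"),
            n_trials=("n_trials", "sum"),
        )
        .reset_index()
    )
    return per_lab


def correlate_bins(binavg: pd.DataFrame, value_col: str = "roi_n400"):
    """Pearson r between bin-average cloze and bin-average amplitude.

    Two-tailed p from t = r * sqrt((n-2)/(1-r^2)) on n-2 df.  Requires at
    least 3 rows; zero variance in either variable yields ``(nan, nan, n)``
    (flagged as undefined rather than raising, so channel maps can skip
    degenerate channels).
    """
    x = binavg["mean_cloze"].to_numpy(dtype=float)
    y = binavg[value_col].to_numpy(dtype=float)
    n = len(binavg)
    if n < 3:
        raise ValueError("need at least 3 bin rows to correlate")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), n
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), n


def corr_map(binavg: pd.DataFrame, channels) -> pd.DataFrame:
    """Per-channel correlation table: columns channel, r, p, n.

    ``channels`` are channel labels whose bin-average columns are named
    ``ch_<label>`` (as produced by the trial-table builder).
    """
    rows = []
    for ch in channels:
        r, p, n = correlate_bins(binavg, f"ch_{ch}")
        rows.append({"channel": ch, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)


def pool_labs(binavgs) -> pd.DataFrame:
    """Concatenate per-lab bin-average tables into one lab x bin table.

    The correlation then runs over (#labs x #occupied bins) points,
    treating laboratories as multiple observations of each bin average.
    """
    frames = list(binavgs)
    if not frames:
        raise ValueError("no bin-average tables to pool")
    return pd.concat(frames, ignore_index=True)


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation.

    z = atanh(r) with standard error 1/sqrt(n-3); the two-tailed normal
    quantile gives the half-width and the bounds map back through tanh.
    """
    if not -1.0 < r < 1.0:
        raise ValueError("need |r| < 1")
    if n <= 3:
        raise ValueError("need n >= 4 for a Fisher-z interval")
    q = stats.norm.ppf(0.5 + level / 2.0)
    z = np.arctanh(r)
    half = q / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))
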