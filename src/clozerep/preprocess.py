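"""Epoch preprocessing: baseline correction, band-pass filtering, automatic
artifact rejection, participant exclusion and window averaging.

The rejection rules implement the automatic screening thresholds used after
manual/ICA cleaning in the multi-lab study: a trial is discarded if any
channel shows a peak-to-peak voltage difference of over 120 uV within any
150 ms window, or a voltage step of over 50 uV/ms between consecutive
samples.  Both thresholds are strict ("over"), evaluated on all channels in
the container by default, with window lengths computed from milliseconds so
any sampling rate works.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from clozerep.epochs import ROI_CHANNELS, EpochSet

__all__ = [
    "baseline_correct",
    "bandpass_binroute",
    "reject_artifacts",
    "window_mean",
    "build_trial_table",
    "exclude_participants",
]

#: Baseline windows in ms relative to word onset, keyed by mode name.
BASELINE_WINDOWS = {"pre100": (-100.0, 0.0), "pre500": (-500.0, 0.0)}

#: Analysis windows (ms) and their trial-table column names.
ROI_WINDOWS = {
    "roi_n400": (200.0, 500.0),
    "roi_prearticle": (-500.0, -100.0),
    "roi_p600": (500.0, 800.0),
}


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Boolean mask of samples with window_start <= t <= window_end.

    Closed on both ends; a small tolerance absorbs floating-point jitter in
    the time axis so boundary samples are always included.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError(f"window {window} has start > end")
    eps = 1e-9
    mask = (times >= lo - eps) & (times <= hi + eps)
    if not mask.any():
        raise ValueError(f"window {window} ms contains no samples "
                         f"(epoch covers {times[0]:.1f}..{times[-1]:.1f} ms)")
    return mask


# ------------------------------------------------------------------ baseline

def baseline_correct(epochs: EpochSet, mode: str = "pre100") -> EpochSet:
    """Subtract the mean pre-stimulus voltage per trial and channel.

    ``mode`` is one of ``none`` (identity), ``pre100`` (-100..0 ms) or
    ``pre500`` (-500..0 ms).  Raises if the baseline window is not covered
    by the epoch span.
    """
    if mode == "none":
        return epochs
    if mode not in BASELINE_WINDOWS:
        raise ValueError(f"unknown baseline mode {mode!r}")
    lo, hi = BASELINE_WINDOWS[mode]
    times = epochs.times
    if lo < times[0] - 1e-9 or hi > times[-1] + 1e-9:
        raise ValueError(
            f"baseline window {lo}..{hi} ms outside epoch span "
            f"{times[0]:.1f}..{times[-1]:.1f} ms"
        )
    mask = _window_mask(times, (lo, hi))
    baseline = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs.copy(data=epochs.data - baseline)


# -------------------------------------------------------------------- filter

def bandpass_binroute(
    epochs: EpochSet,
    low_hz: float = 0.2,
    high_hz: float = 15.0,
    order: int = 4,
) -> EpochSet:
    """Zero-phase Butterworth band-pass (default 0.2-15 Hz, 4th order).

    Applied forward-backward (``sosfiltfilt``) per channel and trial, as in
    the averaging-based replication route; the magnitude response is
    therefore the squared response of the designed filter.
    """
    nyq = epochs.sfreq / 2.0
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(f"high cutoff {high_hz} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=epochs.sfreq, output="sos"
    )
    # pad up to ~3 time constants of the low cutoff; short epochs cannot
    # fully escape the high-pass transient, as with any 0.2 Hz filter
    # applied to segmented data
    padlen = min(
        epochs.n_samples - 2, int(round(3.0 * epochs.sfreq / low_hz))
    )
    filtered = np.empty_like(epochs.data)
    n_trials, n_ch, n_samp = epochs.data.shape
    chunk = max(1, int(2e7) // (n_ch * (n_samp + 2 * padlen)))  # bound padding
    for lo in range(0, n_trials, chunk):
        filtered[lo : lo + chunk] = signal.sosfiltfilt(
            sos, epochs.data[lo : lo + chunk], axis=2, padlen=padlen
        )
    return epochs.copy(data=filtered)


# ----------------------------------------------------------------- rejection

def reject_artifacts(
    epochs: EpochSet,
    p2p_threshold_uv: float = 120.0,
    p2p_window_ms: float = 150.0,
    step_threshold_uv_per_ms: float = 50.0,
    channels=None,
) -> tuple[EpochSet, pd.DataFrame]:
    """Flag and drop trials violating the peak-to-peak or step rules.

    A trial is rejected if on ANY examined channel (all channels by default)
    the max-min range within any sliding ``p2p_window_ms`` window strictly
    exceeds ``p2p_threshold_uv``, or the absolute difference between
    consecutive samples divided by the inter-sample interval in ms strictly
    exceeds ``step_threshold_uv_per_ms``.

    Returns ``(retained_epochs, log)`` where the log has one row per input
    trial: ``trial``, ``decision`` (retain|reject), ``rule``
    (peak_to_peak|step|none), ``channel`` and ``time_ms`` of the first
    violation (earliest sample; peak-to-peak wins ties).
    """
    data = epochs.data
    if channels is not None:
        ch_idx = epochs.channel_indices(channels)
        data = data[:, ch_idx, :]
        ch_labels = [epochs.channels[i] for i in ch_idx]
    else:
        ch_labels = list(epochs.channels)
    times = epochs.times
    n_trials, n_ch, n_samp = data.shape

    # sliding peak-to-peak: window length in samples from the ms spec
    w = max(2, int(round(p2p_window_ms * epochs.sfreq / 1000.0)))
    w = min(w, n_samp)
    dt_ms = 1000.0 / epochs.sfreq

    rows = []
    chunk = max(1, int(5e7) // (n_ch * n_samp))  # bound scratch memory
    for lo in range(0, n_trials, chunk):
        block = data[lo : lo + chunk]
        p2p_viol = (
            maximum_filter1d(block, size=w, axis=2)
            - minimum_filter1d(block, size=w, axis=2)
        ) > p2p_threshold_uv
        step_viol = (
            np.abs(np.diff(block, axis=2)) / dt_ms
        ) > step_threshold_uv_per_ms
        for j in range(block.shape[0]):
            rule, ch, t_ms = "none", "", np.nan
            first_p2p = first_step = n_samp + 1
            ch_p2p = ch_step = -1
            if p2p_viol[j].any():
                flat = np.argwhere(p2p_viol[j])
                k = flat[np.argmin(flat[:, 1])]
                ch_p2p, first_p2p = int(k[0]), int(k[1])
            if step_viol[j].any():
                flat = np.argwhere(step_viol[j])
                k = flat[np.argmin(flat[:, 1])]
                ch_step, first_step = int(k[0]), int(k[1])
            if first_p2p <= first_step and ch_p2p >= 0:
                rule, ch, t_ms = "peak_to_peak", ch_labels[ch_p2p], times[first_p2p]
            elif ch_step >= 0:
                rule, ch, t_ms = "step", ch_labels[ch_step], times[first_step]
            rows.append(
                {
                    "trial": lo + j,
                    "decision": "reject" if rule != "none" else "retain",
                    "rule": rule,
                    "channel": ch,
                    "time_ms": t_ms,
                }
            )
    log = pd.DataFrame(rows)
    retained = epochs.subset((log["decision"] == "retain").to_numpy())
    return retained, log


# ------------------------------------------------------------- window means

def window_mean(
    epochs: EpochSet,
    window: tuple[float, float],
    channels=ROI_CHANNELS,
) -> np.ndarray:
    """Per-trial mean voltage over a closed ms window and a channel set.

    Arithmetic mean over samples with window_start <= t <= window_end, then
    over the named channels (unweighted).
    """
    ch_idx = epochs.channel_indices(channels)
    mask = _window_mask(epochs.times, window)
    return epochs.data[np.ix_(np.arange(epochs.n_trials), ch_idx, np.flatnonzero(mask))].mean(
        axis=(1, 2)
    )


def build_trial_table(
    epochs: EpochSet,
    windows: dict[str, tuple[float, float]] | None = None,
    per_channel_window: tuple[float, float] = (200.0, 500.0),
) -> pd.DataFrame:
    """One row per trial: metadata + ROI window means + per-channel means.

    ``windows`` defaults to the three analysis windows (N400 200-500 ms,
    pre-article -500..-100 ms, P600 500-800 ms) averaged over the six
    centro-parietal ROI channels; windows outside the epoch span are
    skipped.  Per-channel means of ``per_channel_window`` are added as
    ``ch_<label>`` columns for the channel-wise correlation maps.
    """
    if windows is None:
        windows = ROI_WINDOWS
    table = epochs.meta.copy().reset_index(drop=True)
    times = epochs.times
    for name, win in windows.items():
        if win[0] < times[0] - 1e-9 or win[1] > times[-1] + 1e-9:
            continue
        table[name] = window_mean(epochs, win, ROI_CHANNELS)
    mask = _window_mask(times, per_channel_window)
    ch_means = epochs.data[:, :, mask].mean(axis=2)
    for j, lab in enumerate(epochs.channels):
        table[f"ch_{lab}"] = ch_means[:, j]
    return table


# ------------------------------------------------------------- exclusion

def exclude_participants(
    table: pd.DataFrame,
    min_per_type: int = 60,
    total_per_type: int = 80,
) -> pd.DataFrame:
    """Drop all trials of participants with too few retained main trials.

    A participant is excluded when they have fewer than ``min_per_type``
    retained article trials or fewer than ``min_per_type`` retained noun
    trials in the main experiment ("fewer than" is strict: exactly
    ``min_per_type`` of each is retained).  ``total_per_type`` documents the
    designed number of trials per word type and caps ``min_per_type``.
    """
    if min_per_type > total_per_type:
        raise ValueError("min_per_type cannot exceed total_per_type")
    main = table[table["experiment"] == "main"] if "experiment" in table.columns else table
    counts = (
        main.groupby(["subject_id", "word_type"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    for wt in ("article", "noun"):
        if wt not in counts.columns:
            counts[wt] = 0
    ok = counts[(counts["article"] >= min_per_type) & (counts["noun"] >= min_per_type)]
    return table[table["subject_id"].isin(ok.index)].copy()
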