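"""Container for single-trial epoched EEG voltages plus trial metadata.

An :class:`EpochSet` is the in-memory interchange object between the
generator, the preprocessing stages and the trial-table builder.  Voltages
are stored as a dense ``(n_trials, n_channels, n_samples)`` float array in
microvolts; trial metadata is a :class:`pandas.DataFrame` with one row per
trial, aligned positionally with the first axis of the voltage array.

On disk an EpochSet is a directory with

* ``meta.csv``            trial metadata (one row per trial),
* ``voltage.npy``         the voltage array,
* ``epochs.json``         sidecar: shape, channel labels, sampling rate,
                          time-zero index, package version,
* ``ground_truth.csv``    (optional) generator ground truth per trial.

``to_long_csv`` writes a long-format table (trial, channel, time_ms, uv)
for interoperability with other tools; ``to_mne`` converts to an
:class:`mne.EpochsArray` when MNE is installed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: The six centro-parietal region-of-interest channels over which
#: single-trial window means are averaged.
ROI_CHANNELS = ("Cz", "C3", "C4", "Pz", "P3", "P4")

#: Standard 10-20 system montage of the 22 common channels.  The six ROI
#: labels are required; the remaining labels are configuration, not logic.
CHANNELS_22 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC3", "FCz", "FC4",
    "T7", "C3", "Cz", "C4", "T8",
    "CP3", "CPz", "CP4",
    "P3", "Pz", "P4",
    "Oz",
)


@dataclass
class EpochSet:
    """Single-trial epoched EEG voltages with aligned trial metadata.

    Parameters
    ----------
    data:
        Voltage array, shape ``(n_trials, n_channels, n_samples)``, in uV.
    meta:
        Trial metadata, one row per trial (positional alignment; the index
        is preserved through preprocessing so rejected trials can be traced).
    channels:
        Channel labels, length ``n_channels``.
    sfreq:
        Sampling rate in Hz.
    tmin_ms:
        Time of the first sample relative to word onset, in ms.
    ground_truth:
        Optional generator ground truth (clean ROI amplitude, artifact flag),
        aligned with ``meta``.
    """

    data: np.ndarray
    meta: pd.DataFrame
    channels: tuple[str, ...]
    sfreq: float
    tmin_ms: float
    ground_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        if self.data.shape[0] != len(self.meta):
            raise ValueError(
                f"{self.data.shape[0]} trials in data but {len(self.meta)} metadata rows"
            )
        if self.data.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[1]} channels in data but {len(self.channels)} labels"
            )

    # ------------------------------------------------------------------ axes
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to word onset."""
        return self.tmin_ms + np.arange(self.n_samples) * 1000.0 / self.sfreq

    @property
    def time_zero_index(self) -> int:
        """Index of the sample closest to word onset (t = 0 ms)."""
        return int(np.argmin(np.abs(self.times)))

    def channel_indices(self, labels) -> np.ndarray:
        idx = []
        for lab in labels:
            if lab not in self.channels:
                raise KeyError(f"unknown channel label {lab!r}")
            idx.append(self.channels.index(lab))
        return np.asarray(idx, dtype=int)

    # ------------------------------------------------------------------ copy
    def copy(self, data: np.ndarray | None = None) -> "EpochSet":
        return EpochSet(
            data=self.data.copy() if data is None else data,
            meta=self.meta.copy(),
            channels=self.channels,
            sfreq=self.sfreq,
            tmin_ms=self.tmin_ms,
            ground_truth=None if self.ground_truth is None else self.ground_truth.copy(),
        )

    def subset(self, keep: np.ndarray) -> "EpochSet":
        """Return a new EpochSet restricted to a boolean/positional trial mask."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return EpochSet(
            data=self.data[keep],
            meta=self.meta.iloc[keep].copy(),
            channels=self.channels,
            sfreq=self.sfreq,
            tmin_ms=self.tmin_ms,
            ground_truth=(
                None if self.ground_truth is None else self.ground_truth.iloc[keep].copy()
            ),
        )

    # ------------------------------------------------------------------- io
    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.meta.to_csv(outdir / "meta.csv", index=False)
        np.save(outdir / "voltage.npy", self.data)
        sidecar = {
            "shape": list(self.data.shape),
            "channels": list(self.channels),
            "sfreq": self.sfreq,
            "tmin_ms": self.tmin_ms,
            "time_zero_index": self.time_zero_index,
            "units": "microvolt",
        }
        (outdir / "epochs.json").write_text(json.dumps(sidecar, indent=2))
        if self.ground_truth is not None:
            self.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)

    @classmethod
    def load(cls, indir) -> "EpochSet":
        indir = Path(indir)
        sidecar = json.loads((indir / "epochs.json").read_text())
        gt_path = indir / "ground_truth.csv"
        return cls(
            data=np.load(indir / "voltage.npy"),
            meta=pd.read_csv(indir / "meta.csv"),
            channels=tuple(sidecar["channels"]),
            sfreq=float(sidecar["sfreq"]),
            tmin_ms=float(sidecar["tmin_ms"]),
            ground_truth=pd.read_csv(gt_path) if gt_path.exists() else None,
        )

    def to_long_csv(self, path, decimals: int = 4) -> None:
        """Write a long-format (trial, channel, time_ms, uv) CSV."""
        times = self.times
        n_t, n_c, n_s = self.data.shape
        frame = pd.DataFrame(
            {
                "trial": np.repeat(np.arange(n_t), n_c * n_s),
                "channel": np.tile(np.repeat(np.asarray(self.channels), n_s), n_t),
                "time_ms": np.tile(times, n_t * n_c),
                "uv": np.round(self.data.reshape(-1), decimals),
            }
        )
        frame.to_csv(path, index=False)

    def to_mne(self):
        """Convert to :class:`mne.EpochsArray` (volts, metadata attached)."""
        import mne

        info = mne.create_info(list(self.channels), self.sfreq, ch_types="eeg")
        return mne.EpochsArray(
            self.data * 1e-6,
            info,
            tmin=self.tmin_ms / 1000.0,
            metadata=self.meta.reset_index(drop=True),
            verbose="error",
        )
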