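"""Seeded generator of multi-lab single-trial epoched EEG with a known
cloze -> N400 effect.

The generator emulates the design of a nine-laboratory article/noun reading
study: subjects nested in labs, 80 items crossed with subjects, a heavily
skewed cloze-probability distribution (most mass in the lowest decile), a
centro-parietal negative-going component peaking ~400 ms whose 200-500 ms
window-mean amplitude depends linearly on cloze, crossed subject/item random
intercepts and slopes, broadband 1/f background noise, and (optionally)
blink/step artifacts for the rejection stage to catch.  A control session
adds trials whose words follow a grammatical or ungrammatical article; the
ungrammatical ones receive a later positive (P600-like) component peaking
~650 ms.

Calibration contract
--------------------
The clean component template is scaled so that its mean over the six ROI
channels (Cz/C3/C4/Pz/P3/P4) and the 200-500 ms window equals exactly 1.
The latent single-trial amplitude

    a = alpha + (beta + u_subj_slope + w_item_slope) * cloze/100
        + u_subj_int + w_item_int + lab effects + eps

is therefore directly the trial's clean ROI window mean in microvolts, and
``beta`` has the units "uV change from 0% to 100% cloze".  The P600 template
is normalised the same way over the 500-800 ms window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from clozerep.epochs import CHANNELS_22, ROI_CHANNELS, EpochSet

__all__ = [
    "GeneratorParams",
    "make_design",
    "simulate_epochs",
    "simulate_trial_table",
    "inject_artifacts",
]

#: Default cloze decile weights: ~37.5% of trials in the 0-10% bin, ~4% in
#: the 90-100% bin, with the intermediate deciles sparsest.
DEFAULT_DECILE_WEIGHTS = (
    0.375, 0.18, 0.08, 0.05, 0.035, 0.035, 0.045, 0.06, 0.10, 0.04,
)

# Relative scalp weights of the negative centro-parietal component (N400-like)
# and of the later parietal positivity (P600-like).  Configuration, not logic:
# only the ROI normalisation below is load-bearing.
_N400_TOPO = {
    "Fp1": 0.2, "Fp2": 0.2, "F7": 0.35, "F3": 0.45, "Fz": 0.5, "F4": 0.45,
    "F8": 0.35, "FC3": 0.7, "FCz": 0.75, "FC4": 0.7, "T7": 0.5, "C3": 0.9,
    "Cz": 1.0, "C4": 0.9, "T8": 0.5, "CP3": 0.95, "CPz": 1.0, "CP4": 0.95,
    "P3": 0.9, "Pz": 1.0, "P4": 0.9, "Oz": 0.6,
}
_P600_TOPO = {
    "Fp1": 0.1, "Fp2": 0.1, "F7": 0.2, "F3": 0.3, "Fz": 0.35, "F4": 0.3,
    "F8": 0.2, "FC3": 0.5, "FCz": 0.55, "FC4": 0.5, "T7": 0.4, "C3": 0.75,
    "Cz": 0.8, "C4": 0.75, "T8": 0.4, "CP3": 0.9, "CPz": 0.95, "CP4": 0.9,
    "P3": 1.0, "Pz": 1.0, "P4": 1.0, "Oz": 0.8,
}

_ITEM_CONTROL_OFFSET = 100_000  # control items live in their own id range

# Sub-stream keys: each stage draws from default_rng([seed, KEY]) so that
# nearby integer seeds never share a stream between stages.
_KEY_DESIGN, _KEY_VOLTAGE, _KEY_ARTIFACT = 0, 1, 2


@dataclass
class GeneratorParams:
    """All knobs of the synthetic study.

    Amplitudes and standard deviations are in uV on the ROI window-mean
    scale (see the calibration contract in the module docstring); ``beta_*``
    are uV per 0 -> 100% cloze step.
    """

    n_labs: int = 9
    subjects_per_lab: int = 40
    n_items: int = 80
    n_control_items: int = 80
    sampling_rate: float = 250.0
    epoch_span: tuple[float, float] = (-500.0, 1000.0)
    alpha: float = -2.0
    beta_article: float = 0.3
    beta_noun: float = 2.2
    beta_p600: float = 2.0
    sd_subj_int: float = 1.5
    sd_subj_slope: float = 1.0
    sd_item_int: float = 2.0
    sd_item_slope: float = 1.0
    sd_lab_int: float = 0.0
    sd_lab_slope: float = 0.0
    sd_trial: float = 10.0
    noise_exponent: float = 1.0
    noise_sd: float = 5.0
    cloze_decile_weights: tuple[float, ...] = DEFAULT_DECILE_WEIGHTS
    artifact_rate: float = 0.0
    accuracy_mean: float = 0.95
    accuracy_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_labs", "subjects_per_lab", "n_items"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if self.n_control_items < 0:
            raise ValueError("n_control_items must be >= 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.epoch_span[0] >= self.epoch_span[1]:
            raise ValueError("epoch_span must be (start, end) with start < end")
        for name in (
            "sd_subj_int", "sd_subj_slope", "sd_item_int", "sd_item_slope",
            "sd_lab_int", "sd_lab_slope", "sd_trial", "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        w = np.asarray(self.cloze_decile_weights, dtype=float)
        if w.shape != (10,) or (w < 0).any():
            raise ValueError("cloze_decile_weights must be 10 non-negative numbers")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("cloze_decile_weights must sum to 1 within 1e-12")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be in [0, 1]")

    @property
    def n_subjects(self) -> int:
        return self.n_labs * self.subjects_per_lab

    def with_(self, **kwargs) -> "GeneratorParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


# --------------------------------------------------------------------- design

def _draw_cloze(rng: np.random.Generator, n: int, weights) -> np.ndarray:
    """Integer cloze percents: decile from ``weights``, uniform within it.

    Decile 1 covers the integers 0..10, decile k >= 2 covers
    10(k-1)+1 .. 10k, mirroring bins "0-10, 11-20, ..., 91-100".
    """
    deciles = rng.choice(10, size=n, p=np.asarray(weights, dtype=float))
    lo = np.where(deciles == 0, 0, deciles * 10 + 1)
    hi = deciles * 10 + 10  # inclusive
    return rng.integers(lo, hi + 1)


def make_design(params: GeneratorParams) -> pd.DataFrame:
    """Build the trial-level study design (no voltages yet).

    One article row and one noun row per (subject, item) — both words come
    from the same sentence, so each subject sees each item once.  Control
    rows (grammatical/ungrammatical article before the noun) are appended
    with ``experiment == "control"`` and item ids in a separate range.

    Columns: lab_id, subject_id, item_id, word_type, cloze, grammatical,
    subject_accuracy, experiment.
    """
    rng = np.random.default_rng([params.seed, _KEY_DESIGN])

    labs = [f"lab{i + 1}" for i in range(params.n_labs)]
    subjects = [
        (lab, f"{lab}_s{j + 1:02d}")
        for lab in labs
        for j in range(params.subjects_per_lab)
    ]
    cloze_article = _draw_cloze(rng, params.n_items, params.cloze_decile_weights)
    cloze_noun = _draw_cloze(rng, params.n_items, params.cloze_decile_weights)
    cloze_control = _draw_cloze(
        rng, params.n_control_items, params.cloze_decile_weights
    )
    accuracy = np.clip(
        rng.normal(params.accuracy_mean, params.accuracy_sd, size=len(subjects)),
        0.5,
        1.0,
    )

    frames = []
    items = np.arange(1, params.n_items + 1)
    for (lab, subj), acc in zip(subjects, accuracy):
        for word_type, cloze in (("article", cloze_article), ("noun", cloze_noun)):
            frames.append(
                pd.DataFrame(
                    {
                        "lab_id": lab,
                        "subject_id": subj,
                        "item_id": items,
                        "word_type": word_type,
                        "cloze": cloze,
                        "grammatical": True,
                        "subject_accuracy": acc,
                        "experiment": "main",
                    }
                )
            )
        if params.n_control_items:
            # half the control sentences per subject are ungrammatical
            gram = np.ones(params.n_control_items, dtype=bool)
            gram[rng.permutation(params.n_control_items)[: params.n_control_items // 2]] = False
            frames.append(
                pd.DataFrame(
                    {
                        "lab_id": lab,
                        "subject_id": subj,
                        "item_id": np.arange(1, params.n_control_items + 1)
                        + _ITEM_CONTROL_OFFSET,
                        "word_type": "noun",
                        "cloze": cloze_control,
                        "grammatical": gram,
                        "subject_accuracy": acc,
                        "experiment": "control",
                    }
                )
            )
    design = pd.concat(frames, ignore_index=True)
    return design


# ----------------------------------------------------------------- amplitudes

def _trial_amplitudes(
    design: pd.DataFrame, params: GeneratorParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Latent clean window-mean amplitudes for every design row.

    Returns ``(amp_n400, amp_p600)`` in uV.  Subject intercepts/slopes are
    shared across word types (same head, same session); item effects are
    drawn per (item, word_type) because article and noun are different words.
    The trial residual ``eps`` is part of the latent amplitude (it is the
    residual of the window mean, not of single samples).
    """
    subj_codes, subj_levels = pd.factorize(design["subject_id"], sort=True)
    item_key = design["item_id"].astype(str) + ":" + design["word_type"]
    item_codes, item_levels = pd.factorize(item_key, sort=True)
    lab_codes, lab_levels = pd.factorize(design["lab_id"], sort=True)

    u_int = rng.normal(0.0, params.sd_subj_int, len(subj_levels))
    u_slope = rng.normal(0.0, params.sd_subj_slope, len(subj_levels))
    w_int = rng.normal(0.0, params.sd_item_int, len(item_levels))
    w_slope = rng.normal(0.0, params.sd_item_slope, len(item_levels))
    l_int = rng.normal(0.0, params.sd_lab_int, len(lab_levels))
    l_slope = rng.normal(0.0, params.sd_lab_slope, len(lab_levels))

    cloze01 = design["cloze"].to_numpy(dtype=float) / 100.0
    beta = np.where(
        design["word_type"].to_numpy() == "article",
        params.beta_article,
        params.beta_noun,
    )
    eps = rng.normal(0.0, params.sd_trial, len(design))
    amp_n400 = (
        params.alpha
        + (beta + u_slope[subj_codes] + w_slope[item_codes] + l_slope[lab_codes])
        * cloze01
        + u_int[subj_codes]
        + w_int[item_codes]
        + l_int[lab_codes]
        + eps
    )

    is_control = (design["experiment"] == "control").to_numpy()
    ungram = is_control & ~design["grammatical"].to_numpy()
    eps_p600 = rng.normal(0.0, params.sd_trial, len(design))
    amp_p600 = np.where(
        is_control, params.beta_p600 * ungram.astype(float) + eps_p600, 0.0
    )
    return amp_n400, amp_p600


# ------------------------------------------------------------------ templates

def _component_template(
    times: np.ndarray,
    channels: tuple[str, ...],
    topo: dict[str, float],
    peak_ms: float,
    width_ms: float,
    norm_window: tuple[float, float],
) -> np.ndarray:
    """Spatial x temporal template normalised to ROI window mean == 1."""
    temporal = np.exp(-0.5 * ((times - peak_ms) / width_ms) ** 2)
    spatial = np.array([topo[c] for c in channels], dtype=float)
    template = np.outer(spatial, temporal)
    roi = [channels.index(c) for c in ROI_CHANNELS]
    mask = (times >= norm_window[0]) & (times <= norm_window[1])
    scale = template[np.ix_(roi, np.flatnonzero(mask))].mean()
    return template / scale


def _pink_noise(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n_samples: int,
    exponent: float,
    sd: float,
    sfreq: float,
) -> np.ndarray:
    """1/f^a background noise, exact per-trace RMS ``sd`` (uV)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    weights = np.zeros_like(freqs)
    weights[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (
        rng.standard_normal((*shape, len(freqs)))
        + 1j * rng.standard_normal((*shape, len(freqs)))
    ) * weights
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    rms = x.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return sd * x / rms


# -------------------------------------------------------------------- epochs

def simulate_epochs(
    design: pd.DataFrame,
    params: GeneratorParams,
    seed: int | None = None,
) -> EpochSet:
    """Synthesize voltage epochs for every design row.

    ``voltage = template * amplitude (+ P600 template * p600 amplitude)
    + 1/f noise``; the templates obey the calibration contract (module
    docstring), so the clean ROI window mean of each trial equals its latent
    amplitude exactly.

    The voltage stream is keyed separately from the design stream, so the
    same ``params.seed`` yields independent design and voltage draws.
    """
    required = {"lab_id", "subject_id", "item_id", "word_type", "cloze", "experiment"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design is missing columns: {sorted(missing)}")
    if design["lab_id"].nunique() > params.n_labs:
        raise ValueError("design has more labs than params.n_labs")

    rng = np.random.default_rng(
        [params.seed if seed is None else seed, _KEY_VOLTAGE]
    )
    start, end = params.epoch_span
    n_samples = int(round((end - start) * params.sampling_rate / 1000.0)) + 1
    times = start + np.arange(n_samples) * 1000.0 / params.sampling_rate

    n400 = _component_template(
        times, CHANNELS_22, _N400_TOPO, peak_ms=400.0, width_ms=70.0,
        norm_window=(200.0, 500.0),
    )
    p600 = _component_template(
        times, CHANNELS_22, _P600_TOPO, peak_ms=650.0, width_ms=90.0,
        norm_window=(500.0, 800.0),
    )

    amp_n400, amp_p600 = _trial_amplitudes(design, params, rng)

    n_trials = len(design)
    data = np.empty((n_trials, len(CHANNELS_22), n_samples))
    chunk = max(1, int(2e7) // (len(CHANNELS_22) * n_samples))  # bound peak memory
    for lo in range(0, n_trials, chunk):
        hi = min(lo + chunk, n_trials)
        block = amp_n400[lo:hi, None, None] * n400[None, :, :]
        p600_amps = amp_p600[lo:hi]
        if np.any(p600_amps):
            block = block + p600_amps[:, None, None] * p600[None, :, :]
        if params.noise_sd > 0:
            block = block + _pink_noise(
                rng,
                (hi - lo, len(CHANNELS_22)),
                n_samples,
                params.noise_exponent,
                params.noise_sd,
                params.sampling_rate,
            )
        data[lo:hi] = block

    ground_truth = pd.DataFrame(
        {
            "clean_amp": amp_n400,
            "clean_amp_p600": amp_p600,
            "artifact": False,
            "artifact_kind": "none",
        }
    )
    return EpochSet(
        data=data,
        meta=design.reset_index(drop=True),
        channels=CHANNELS_22,
        sfreq=params.sampling_rate,
        tmin_ms=start,
        ground_truth=ground_truth,
    )


def simulate_trial_table(
    design: pd.DataFrame,
    params: GeneratorParams,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fast table-level path: draw ROI window means without waveforms.

    Returns the design plus ``roi_n400``, ``roi_prearticle`` and ``roi_p600``
    columns drawn from the same latent amplitude model that
    :func:`simulate_epochs` uses.  Differences from the epoch path: the
    residual is ``sd_trial`` only (no background-noise window mean), the
    pre-article window is pure N(0, sd_trial) noise, and the N400 template
    tail does not leak into the P600 window.  Intended for large simulation
    studies (power, type-I error, coverage) where waveform synthesis would
    dominate the cost.
    """
    rng = np.random.default_rng(
        [params.seed if seed is None else seed, _KEY_VOLTAGE]
    )
    amp_n400, amp_p600 = _trial_amplitudes(design, params, rng)
    table = design.copy().reset_index(drop=True)
    table["roi_n400"] = amp_n400
    table["roi_prearticle"] = rng.normal(0.0, params.sd_trial, len(table))
    table["roi_p600"] = amp_p600
    return table


# ------------------------------------------------------------------ artifacts

BLINK_AMPLITUDE_UV = 150.0
BLINK_WIDTH_MS = 35.0
STEP_SLOPE_UV_PER_MS = 60.0

_BLINK_TOPO = {
    "Fp1": 1.0, "Fp2": 1.0, "F7": 0.45, "F3": 0.45, "Fz": 0.45, "F4": 0.45,
    "F8": 0.45, "FC3": 0.2, "FCz": 0.2, "FC4": 0.2,
}


def inject_artifacts(
    epochs: EpochSet,
    params: GeneratorParams,
    seed: int | None = None,
) -> EpochSet:
    """Contaminate a random ``artifact_rate`` fraction of trials.

    Half of the selected trials receive a blink-like frontal deflection
    (peak 150 uV, well over the 120 uV / 150 ms peak-to-peak rejection
    threshold); the other half receive a single-sample step whose slope
    exceeds 50 uV/ms.  Injected trials are flagged in ``ground_truth``.
    With ``artifact_rate == 0`` the input is returned unchanged (same data).
    """
    if params.artifact_rate == 0:
        return epochs
    rng = np.random.default_rng(
        [params.seed if seed is None else seed, _KEY_ARTIFACT]
    )
    out = epochs.copy()
    times = out.times
    hit = rng.random(out.n_trials) < params.artifact_rate
    kinds = np.where(rng.random(out.n_trials) < 0.5, "blink", "step")

    blink_spatial = np.array(
        [_BLINK_TOPO.get(c, 0.0) for c in out.channels], dtype=float
    )
    for i in np.flatnonzero(hit):
        if kinds[i] == "blink":
            center = rng.uniform(times[0] + 100.0, times[-1] - 100.0)
            pulse = BLINK_AMPLITUDE_UV * np.exp(
                -0.5 * ((times - center) / BLINK_WIDTH_MS) ** 2
            )
            out.data[i] += blink_spatial[:, None] * pulse[None, :]
        else:
            ch = rng.integers(out.data.shape[1])
            k = rng.integers(out.n_samples // 4, 3 * out.n_samples // 4)
            dt_ms = 1000.0 / out.sfreq
            out.data[i, ch, k:] += STEP_SLOPE_UV_PER_MS * dt_ms
    if out.ground_truth is None:
        out.ground_truth = pd.DataFrame(index=range(out.n_trials))
    out.ground_truth["artifact"] = hit
    out.ground_truth["artifact_kind"] = np.where(hit, kinds, "none")
    return out
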