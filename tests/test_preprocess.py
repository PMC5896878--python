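"""Preprocessing: baselines, the band-pass filter, rejection rules,
participant exclusion and window means."""

import numpy as np
import pandas as pd
import pytest

from clozerep.epochs import ROI_CHANNELS
from clozerep.generator import GeneratorParams, inject_artifacts, make_design, simulate_epochs
from clozerep.preprocess import (
    bandpass_binroute,
    baseline_correct,
    build_trial_table,
    exclude_participants,
    reject_artifacts,
    window_mean,
)
from helpers import constant_epochs, ramp_epochs


class TestBaseline:
    def test_constant_epoch_becomes_zero(self):
        ep = baseline_correct(constant_epochs(7.0), "pre100")
        assert np.allclose(ep.data, 0.0, atol=1e-12)

    def test_mode_none_is_identity(self, flat_epochs):
        assert baseline_correct(flat_epochs, "none") is flat_epochs

    def test_ramp_shifts_by_plus_fifty(self):
        # v(t) = t; mean over -100..0 ms is -50, so correction adds +50
        ep = baseline_correct(ramp_epochs(), "pre100")
        t0 = ep.time_zero_index
        assert ep.data[0, 0, t0] == pytest.approx(50.0, abs=1e-9)

    def test_baseline_window_mean_zero_after_correction(self, tiny_epochs):
        for mode, window in [("pre100", (-100.0, 0.0)), ("pre500", (-500.0, 0.0))]:
            ep = baseline_correct(tiny_epochs, mode)
            mask = (ep.times >= window[0] - 1e-9) & (ep.times <= window[1] + 1e-9)
            means = ep.data[:, :, mask].mean(axis=2)
            assert np.abs(means).max() < 1e-9

    def test_window_outside_span_raises(self):
        ep = constant_epochs(1.0)
        ep.tmin_ms = -50.0  # epoch now starts at -50 ms
        with pytest.raises(ValueError, match="outside epoch span"):
            baseline_correct(ep, "pre100")


class TestBandpass:
    @staticmethod
    def _long_sine_epochs(freq_hz: float, sfreq: float = 250.0, seconds: float = 24.0):
        """One long epoch so the 0.2 Hz high-pass transient can decay."""
        from clozerep.epochs import CHANNELS_22, EpochSet

        n = int(seconds * sfreq) + 1
        t = np.arange(n) / sfreq
        data = np.sin(2 * np.pi * freq_hz * t)[None, None, :].repeat(
            len(CHANNELS_22), axis=1
        )
        meta = pd.DataFrame({"subject_id": ["s0"], "word_type": ["article"]})
        return EpochSet(data=data.copy(), meta=meta, channels=CHANNELS_22,
                        sfreq=sfreq, tmin_ms=0.0)

    def test_dc_removed(self):
        out = bandpass_binroute(constant_epochs(10.0, n_trials=1))
        assert abs(out.data.mean()) < 0.1  # zero gain at 0 Hz

    def test_magnitude_response(self):
        # two zero-phase passes square the designed magnitude response
        from scipy import signal

        sos = signal.butter(4, [0.2, 15.0], btype="bandpass", fs=250.0, output="sos")
        _, h = signal.sosfreqz(sos, worN=[5.0, 50.0], fs=250.0)
        assert np.abs(h[0]) ** 2 == pytest.approx(1.0, rel=0.05)
        assert np.abs(h[1]) ** 2 < 0.01

    def test_passband_5hz_preserved_in_time_domain(self):
        out = bandpass_binroute(self._long_sine_epochs(5.0))
        mid = slice(out.n_samples // 3, 2 * out.n_samples // 3)
        amp = np.ptp(out.data[0, 0, mid]) / 2
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_stopband_50hz_rejected_in_time_domain(self):
        out = bandpass_binroute(self._long_sine_epochs(50.0))
        mid = slice(out.n_samples // 3, 2 * out.n_samples // 3)
        assert np.abs(out.data[0, 0, mid]).max() < 0.01

    def test_cutoff_above_nyquist_raises(self):
        ep = constant_epochs(0.0, sfreq=25.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_binroute(ep)


class TestRejection:
    def test_flat_epoch_retained(self, flat_epochs):
        retained, log = reject_artifacts(flat_epochs)
        assert retained.n_trials == flat_epochs.n_trials
        assert (log["decision"] == "retain").all()
        assert (log["rule"] == "none").all()

    def test_every_trial_logged_once(self, tiny_epochs):
        _, log = reject_artifacts(tiny_epochs)
        assert len(log) == tiny_epochs.n_trials
        assert log["trial"].is_unique

    def test_peak_to_peak_boundary(self):
        # smooth 100 ms half-sine bumps of 119 vs 121 uV at 1000 Hz
        for amp, decision in [(119.0, "retain"), (121.0, "reject")]:
            ep = constant_epochs(0.0, n_trials=1, sfreq=1000.0)
            mask = (ep.times >= 100) & (ep.times <= 200)
            phase = np.linspace(0, np.pi, mask.sum())
            ep.data[0, 5, mask] = amp * np.sin(phase)
            _, log = reject_artifacts(ep)
            assert log.loc[0, "decision"] == decision, amp
            if decision == "reject":
                assert log.loc[0, "rule"] == "peak_to_peak"

    def test_step_boundary(self):
        # single-sample steps of 49 vs 51 uV/ms at 1000 Hz (dt = 1 ms)
        for slope, decision in [(49.0, "retain"), (51.0, "reject")]:
            ep = constant_epochs(0.0, n_trials=1, sfreq=1000.0)
            ep.data[0, 3, 700:] += slope * 1.0
            _, log = reject_artifacts(ep)
            assert log.loc[0, "decision"] == decision, slope
            if decision == "reject":
                assert log.loc[0, "rule"] == "step"

    def test_130uv_swing_rejected_as_peak_to_peak(self):
        ep = constant_epochs(0.0, n_trials=1, sfreq=1000.0)
        mask = (ep.times >= 0) & (ep.times <= 100)
        ep.data[0, 0, mask] = 130.0 * np.sin(np.linspace(0, np.pi, mask.sum()))
        _, log = reject_artifacts(ep)
        assert log.loc[0, "decision"] == "reject"
        assert log.loc[0, "rule"] == "peak_to_peak"

    def test_threshold_monotonicity(self, tiny_epochs):
        # stricter thresholds can only reject more trials
        _, log_default = reject_artifacts(tiny_epochs, 120.0, 150.0, 50.0)
        _, log_strict = reject_artifacts(tiny_epochs, 60.0, 150.0, 25.0)
        rej_default = set(log_default.loc[log_default["decision"] == "reject", "trial"])
        rej_strict = set(log_strict.loc[log_strict["decision"] == "reject", "trial"])
        assert rej_default <= rej_strict

    def test_perfect_sensitivity_and_specificity_on_generator(self):
        params = GeneratorParams(
            n_labs=1, subjects_per_lab=4, n_items=20, n_control_items=0,
            noise_sd=3.0, sd_trial=5.0, artifact_rate=0.3, seed=21,
        )
        epochs = simulate_epochs(make_design(params), params)
        epochs = inject_artifacts(epochs, params)
        truth = epochs.ground_truth["artifact"].to_numpy()
        _, log = reject_artifacts(epochs)
        flagged = (log["decision"] == "reject").to_numpy()
        assert np.array_equal(flagged, truth)


class TestWindowMean:
    def test_constant(self):
        vals = window_mean(constant_epochs(5.0), (200.0, 500.0))
        assert np.allclose(vals, 5.0)

    def test_ramp_over_200_500_is_350(self):
        vals = window_mean(ramp_epochs(), (200.0, 500.0))
        assert vals[0] == pytest.approx(350.0, abs=1e-9)

    def test_single_channel_degenerate_set(self, tiny_epochs):
        cz = tiny_epochs.channels.index("Cz")
        mask = (tiny_epochs.times >= 200 - 1e-9) & (tiny_epochs.times <= 500 + 1e-9)
        expected = tiny_epochs.data[:, cz, mask].mean(axis=1)
        np.testing.assert_allclose(window_mean(tiny_epochs, (200, 500), ["Cz"]), expected)

    def test_unknown_channel_raises(self, flat_epochs):
        with pytest.raises(KeyError, match="unknown channel"):
            window_mean(flat_epochs, (200, 500), ["Nope"])

    def test_linearity_with_baseline(self, tiny_epochs):
        # window mean after pre100 baseline == window mean before minus baseline
        before = window_mean(tiny_epochs, (200, 500))
        baselined = baseline_correct(tiny_epochs, "pre100")
        after = window_mean(baselined, (200, 500))
        base = window_mean(tiny_epochs, (-100.0, 0.0))
        np.testing.assert_allclose(after, before - base, atol=1e-9)

    def test_roi_is_unweighted_channel_mean(self, tiny_epochs):
        table = build_trial_table(tiny_epochs)
        per_channel = np.column_stack(
            [window_mean(tiny_epochs, (200, 500), [c]) for c in ROI_CHANNELS]
        )
        np.testing.assert_allclose(
            table["roi_n400"].to_numpy(), per_channel.mean(axis=1), atol=1e-9
        )


class TestExclusion:
    @staticmethod
    def _table(counts: dict) -> pd.DataFrame:
        rows = []
        for subj, (n_art, n_noun) in counts.items():
            for wt, n in [("article", n_art), ("noun", n_noun)]:
                for i in range(n):
                    rows.append(
                        {"subject_id": subj, "word_type": wt, "item_id": i,
                         "experiment": "main", "cloze": 10, "roi_n400": 0.0}
                    )
        return pd.DataFrame(rows)

    def test_fifty_nine_articles_excluded_entirely(self):
        table = self._table({"a": (59, 80), "b": (80, 80)})
        out = exclude_participants(table)
        assert set(out["subject_id"]) == {"b"}

    def test_exactly_sixty_retained(self):
        table = self._table({"a": (60, 60)})
        out = exclude_participants(table)
        assert len(out) == len(table)

    def test_all_above_threshold_is_identity(self):
        table = self._table({"a": (70, 80), "b": (61, 62)})
        out = exclude_participants(table)
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True), table.reset_index(drop=True)
        )

    def test_min_above_total_raises(self):
        with pytest.raises(ValueError):
            exclude_participants(self._table({"a": (80, 80)}), 90, 80)
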