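"""Bin route: decile assignment, grand averages vs a brute-force oracle,
correlations vs the definition formula, pooling, Fisher-z intervals."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_h

from clozerep.binrep import (
    assign_bin,
    correlate_bins,
    corr_map,
    fisher_ci,
    grand_bin_averages,
    pool_labs,
)


class TestAssignBin:
    @pytest.mark.parametrize(
        "cloze,expected",
        [(0, 1), (10, 1), (11, 2), (20, 2), (21, 3), (55, 6), (91, 10), (100, 10)],
    )
    def test_examples(self, cloze, expected):
        assert assign_bin(cloze) == expected

    def test_out_of_range_raises(self):
        for bad in (-1, 101, np.nan):
            with pytest.raises(ValueError):
                assign_bin(bad)

    @given(st_h.integers(min_value=0, max_value=100))
    @settings(derandomize=True, max_examples=101)
    def test_bin_interval_property(self, cloze):
        k = assign_bin(cloze)
        lo = 0 if k == 1 else 10 * (k - 1) + 1
        assert lo <= cloze <= 10 * k


def _random_trial_table(rng, n_labs=2, n_subj=4, n_trials=60):
    rows = []
    for lab in range(n_labs):
        for s in range(n_subj):
            for _ in range(n_trials):
                rows.append(
                    {
                        "lab_id": f"lab{lab}",
                        "subject_id": f"lab{lab}_s{s}",
                        "cloze": int(rng.integers(0, 101)),
                        "roi_n400": float(rng.normal()),
                    }
                )
    return pd.DataFrame(rows)


def _brute_force_bin_averages(table):
    """Nested-loop oracle for the within/across-participant averaging."""
    out = []
    for lab in sorted(table["lab_id"].unique()):
        for b in range(1, 11):
            subj_amp, subj_cloze, n_trials = [], [], 0
            for subj in sorted(table.loc[table["lab_id"] == lab, "subject_id"].unique()):
                amps, clozes = [], []
                sub = table[(table["lab_id"] == lab) & (table["subject_id"] == subj)]
                for _, row in sub.iterrows():
                    if assign_bin(row["cloze"]) == b:
                        amps.append(row["roi_n400"])
                        clozes.append(row["cloze"])
                if amps:
                    subj_amp.append(np.mean(amps))
                    subj_cloze.append(np.mean(clozes))
                    n_trials += len(amps)
            if subj_amp:
                out.append(
                    {
                        "lab_id": lab,
                        "bin_index": b,
                        "mean_cloze": np.mean(subj_cloze),
                        "roi_n400": np.mean(subj_amp),
                        "n_participants": len(subj_amp),
                        "n_trials": n_trials,
                    }
                )
    return pd.DataFrame(out)


class TestGrandBinAverages:
    def test_matches_brute_force_oracle(self):
        table = _random_trial_table(np.random.default_rng(31))
        got = grand_bin_averages(table)
        expected = _brute_force_bin_averages(table)
        got = got.sort_values(["lab_id", "bin_index"]).reset_index(drop=True)
        expected = expected.sort_values(["lab_id", "bin_index"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            got[expected.columns].astype({"n_trials": np.int64}), expected.astype({"n_trials": np.int64}),
            check_dtype=False, atol=1e-12,
        )

    def test_participants_weighted_equally(self):
        # 3 vs 30 trials in the same bin: bin mean is (m1+m2)/2, not trial-weighted
        rows = [{"lab_id": "L", "subject_id": "a", "cloze": 5, "roi_n400": 0.0}] * 3
        rows += [{"lab_id": "L", "subject_id": "b", "cloze": 5, "roi_n400": 10.0}] * 30
        out = grand_bin_averages(pd.DataFrame(rows))
        assert out.loc[0, "roi_n400"] == pytest.approx(5.0)

    def test_single_participant_equals_own_averages(self):
        table = _random_trial_table(np.random.default_rng(7), n_labs=1, n_subj=1)
        out = grand_bin_averages(table)
        table = table.assign(b=assign_bin(table["cloze"].to_numpy()))
        for _, row in out.iterrows():
            sub = table[table["b"] == row["bin_index"]]
            assert row["roi_n400"] == pytest.approx(sub["roi_n400"].mean())

    def test_empty_bins_absent(self):
        table = pd.DataFrame(
            {"lab_id": "L", "subject_id": "a", "cloze": [5, 95], "roi_n400": [1.0, 2.0]}
        )
        out = grand_bin_averages(table)
        assert sorted(out["bin_index"]) == [1, 10]

    def test_mean_cloze_inside_bin(self):
        table = _random_trial_table(np.random.default_rng(13))
        out = grand_bin_averages(table)
        for _, row in out.iterrows():
            k = row["bin_index"]
            lo = 0 if k == 1 else 10 * (k - 1)
            assert lo <= row["mean_cloze"] <= 10 * k

    def test_bin_mass_conservation(self):
        table = _random_trial_table(np.random.default_rng(17))
        out = grand_bin_averages(table)
        assert out["n_trials"].sum() == len(table)


class TestCorrelateBins:
    def test_perfect_linearity(self):
        binavg = pd.DataFrame({"mean_cloze": np.arange(10.0), "roi_n400": 2 * np.arange(10.0) - 3})
        r, p, n = correlate_bins(binavg)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert n == 10

    def test_matches_sum_formula_oracle(self):
        rng = np.random.default_rng(23)
        x, y = rng.normal(size=5), rng.normal(size=5)
        binavg = pd.DataFrame({"mean_cloze": x, "roi_n400": y})
        r, p, n = correlate_bins(binavg)
        # direct definition: sums only
        sx, sy = x.sum(), y.sum()
        sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
        r_oracle = (5 * sxy - sx * sy) / np.sqrt((5 * sxx - sx**2) * (5 * syy - sy**2))
        assert r == pytest.approx(r_oracle, abs=1e-12)
        # p from the t transform
        from scipy import stats as sps

        t = r_oracle * np.sqrt(3 / (1 - r_oracle**2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), 3), abs=1e-12)

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(29)
        binavg = pd.DataFrame({"mean_cloze": rng.normal(size=8), "roi_n400": rng.normal(size=8)})
        r1, p1, _ = correlate_bins(binavg)
        binavg["roi_n400"] *= -1
        r2, p2, _ = correlate_bins(binavg)
        assert r2 == pytest.approx(-r1, abs=1e-12)
        assert p2 == pytest.approx(p1, abs=1e-12)

    def test_zero_variance_flagged(self):
        binavg = pd.DataFrame({"mean_cloze": [1.0, 2.0, 3.0], "roi_n400": [5.0, 5.0, 5.0]})
        r, p, n = correlate_bins(binavg)
        assert np.isnan(r) and np.isnan(p)

    def test_too_few_rows_raise(self):
        binavg = pd.DataFrame({"mean_cloze": [1.0, 2.0], "roi_n400": [0.0, 1.0]})
        with pytest.raises(ValueError, match="at least 3"):
            correlate_bins(binavg)


class TestPooling:
    @staticmethod
    def _nine_lab_table(article: bool):
        # articles never land in the 40-50% bin; nouns occupy all ten
        cloze_values = [5, 15, 25, 35, 55, 65, 75, 85, 95] if article else \
                       [5, 15, 25, 35, 45, 55, 65, 75, 85, 95]
        rng = np.random.default_rng(41)
        rows = []
        for lab in range(9):
            for s in range(2):
                for c in cloze_values:
                    rows.append(
                        {"lab_id": f"lab{lab}", "subject_id": f"lab{lab}_s{s}",
                         "cloze": c, "roi_n400": float(rng.normal())}
                    )
        return pd.DataFrame(rows)

    def test_nine_labs_articles_81_rows(self):
        binavg = grand_bin_averages(self._nine_lab_table(article=True))
        assert len(pool_labs([binavg])) == 81  # 9 labs x 9 occupied bins

    def test_nine_labs_nouns_90_rows(self):
        binavg = grand_bin_averages(self._nine_lab_table(article=False))
        assert len(pool_labs([binavg])) == 90

    def test_single_lab_identity(self):
        binavg = grand_bin_averages(_random_trial_table(np.random.default_rng(3), n_labs=1))
        pd.testing.assert_frame_equal(pool_labs([binavg]), binavg)

    def test_pooled_correlation_invariant_to_lab_order(self):
        table = _random_trial_table(np.random.default_rng(5), n_labs=3)
        per_lab = [
            grand_bin_averages(table[table["lab_id"] == lab])
            for lab in ("lab0", "lab1", "lab2")
        ]
        r1, _, _ = correlate_bins(pool_labs(per_lab))
        r2, _, _ = correlate_bins(pool_labs(per_lab[::-1]))
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestFisherCI:
    def test_printed_interval_reproduced(self):
        lo, hi = fisher_ci(0.68, 10)
        assert round(lo, 2) == 0.09
        assert round(hi, 2) == 0.92

    def test_symmetric_about_zero(self):
        lo, hi = fisher_ci(0.0, 1000)
        assert lo == pytest.approx(-hi, abs=1e-12)

    def test_matches_monte_carlo_sampling_interval(self):
        # r = 0.5, n = 50: quantiles of the sampling distribution of r,
        # 1e5 bivariate-normal resamples, approximate the Fisher interval
        rng = np.random.default_rng(101)
        n, rho, reps = 50, 0.5, 100_000
        x = rng.standard_normal((reps, n))
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal((reps, n))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(axis=1) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        mc_lo, mc_hi = np.quantile(r, [0.025, 0.975])
        lo, hi = fisher_ci(rho, n)
        assert lo == pytest.approx(mc_lo, abs=0.02)
        assert hi == pytest.approx(mc_hi, abs=0.02)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            fisher_ci(1.0, 10)
        with pytest.raises(ValueError):
            fisher_ci(0.5, 3)


def test_corr_map_runs_per_channel():
    rng = np.random.default_rng(51)
    table = _random_trial_table(rng)
    table["ch_Cz"] = rng.normal(size=len(table))
    table["ch_Pz"] = rng.normal(size=len(table))
    binavg = grand_bin_averages(table, ["ch_Cz", "ch_Pz"])
    cm = corr_map(binavg, ["Cz", "Pz"])
    assert list(cm["channel"]) == ["Cz", "Pz"]
    assert ((cm["r"].abs() <= 1) | cm["r"].isna()).all()
    assert (cm["n"] >= 3).all()
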