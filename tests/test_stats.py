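"""Phase contrasts, frequency shifts, the subject score and correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bbphi.stats import (
    correlate,
    main_complex_frequency_diff,
    mip_cut_frequency_diff,
    peak_end_summary,
    phase_contrast,
    rhi_index,
    s_statistic,
    welch_test,
)

from conftest import make_series


class TestWelch:
    def test_textbook_oracle(self):
        # hand computation: means 0.5 vs 1.5, var 1/3 each (ddof=1),
        # se = sqrt(1/6), t = -sqrt(6), Welch-Satterthwaite df = 6
        t, df, p = welch_test(np.array([0, 0, 1, 1.0]), np.array([1, 1, 2, 2.0]))
        assert t == pytest.approx(-np.sqrt(6), abs=1e-9)
        assert df == pytest.approx(6.0, abs=1e-9)
        assert p == pytest.approx(2 * sps.t.sf(np.sqrt(6), 6), abs=1e-12)

    def test_too_few_values_errors(self):
        with pytest.raises(ValueError):
            welch_test(np.array([1.0]), np.array([1.0, 2.0]))

    def test_type_one_error_rate_near_alpha(self):
        # identically distributed samples: the Welch machinery rejects ~5%
        rng = np.random.default_rng(42)
        reps = 500
        hits = sum(
            welch_test(rng.standard_normal(30), rng.standard_normal(30))[2] < 0.05
            for _ in range(reps)
        )
        rate = hits / reps
        ci = 3 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < ci

    def test_phase_contrast_null_never_anticonservative(self):
        # detrending couples the phases slightly, which makes the pooled
        # contrast conservative under the null — but never inflated
        rng = np.random.default_rng(43)
        reps = 300
        hits = 0
        for _ in range(reps):
            s = make_series("s", "SYNC", rng.standard_normal(90))
            pc = phase_contrast({"s": s}, "phi_mip")
            p = pc.tests.set_index(["phase_a", "phase_b"]).loc[("pre", "stim"), "p"]
            hits += p < 0.05
        assert hits / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


class TestPhaseContrast:
    def test_detects_imposed_stim_shift(self):
        rng = np.random.default_rng(1)
        series = {}
        for i in range(5):
            x = rng.standard_normal(90)
            x[30:60] -= 0.5  # stim phase shifted down half a sigma
            series[f"s{i}"] = make_series(f"s{i}", "SYNC", x)
        pc = phase_contrast(series, "phi_mip")
        row = pc.tests.set_index(["phase_a", "phase_b"]).loc[("pre", "stim")]
        assert row.t > 0 and row.p < 1e-6  # pre above stim
        assert pc.phase_means["stim"] < pc.phase_means["pre"]

    def test_pools_across_subjects(self):
        rng = np.random.default_rng(2)
        series = {f"s{i}": make_series(f"s{i}", "SYNC", rng.standard_normal(9))
                  for i in range(4)}
        pc = phase_contrast(series, "phi_mip")
        assert pc.phase_counts == {"pre": 12, "stim": 12, "post": 12}


class TestFrequencyDiffs:
    def _series_with_cuts(self, pre_cuts, stim_cuts):
        n = len(pre_cuts) + len(stim_cuts)
        cuts = list(pre_cuts) + list(stim_cuts) + []
        phi = np.zeros(len(cuts))
        return make_series("s0", "SYNC", phi, cuts=cuts,
                           max_mains=cuts, n_steps=int(len(cuts) * 1.5))

    def test_identical_cut_distributions_give_zero(self):
        s = self._series_with_cuts(["Oz", "Fz"] * 3, ["Oz", "Fz"] * 3)
        diffs = mip_cut_frequency_diff({"s0": s}, "SYNC")
        assert all(abs(d.diff) < 1e-12 for d in diffs)

    def test_shifted_cut_ranks_first_and_sums_to_zero(self):
        s = self._series_with_cuts(["Fz", "Cz", "Fz", "Cz"], ["Oz", "Oz", "Oz", "Fz"])
        diffs = mip_cut_frequency_diff({"s0": s}, "SYNC")
        assert diffs[0].key == "Oz" and diffs[0].diff == pytest.approx(0.75)
        assert sum(d.diff for d in diffs) == pytest.approx(0.0, abs=1e-12)

    def test_main_complex_variant_uses_max_main(self):
        s = self._series_with_cuts(["Fz+Cz"] * 4, ["RES+EDA"] * 4)
        diffs = main_complex_frequency_diff({"s0": s}, "SYNC")
        assert diffs[0].key == "RES+EDA" and diffs[0].diff == pytest.approx(1.0)

    def test_unknown_condition_errors(self):
        s = self._series_with_cuts(["Fz"], ["Fz"])
        with pytest.raises(ValueError):
            mip_cut_frequency_diff({"s0": s}, "ASYNC")


class TestSStatistic:
    def test_identical_conditions_give_zero(self):
        x = np.arange(9, dtype=float)
        sync = make_series("s", "SYNC", x)
        asyn = make_series("s", "ASYNC", x)
        assert s_statistic(sync, asyn) == pytest.approx(0.0, abs=1e-12)

    def test_two_step_toy_value(self):
        # baseline-subtracted stim values sync {0.2, 0.3}, async {0.1, 0.1}
        sync = make_series("s", "SYNC", np.array([0.0, 0.0, 0.2, 0.3, 0.0, 0.0]))
        asyn = make_series("s", "ASYNC", np.array([0.0, 0.0, 0.1, 0.1, 0.0, 0.0]))
        assert s_statistic(sync, asyn) == pytest.approx(0.3, abs=1e-12)

    def test_invariant_to_condition_wide_constant(self, rng):
        x = rng.standard_normal(9)
        y = rng.standard_normal(9)
        base = s_statistic(make_series("s", "SYNC", x), make_series("s", "ASYNC", y))
        shifted = s_statistic(
            make_series("s", "SYNC", x + 5.0), make_series("s", "ASYNC", y)
        )
        assert shifted == pytest.approx(base, abs=1e-10)

    def test_antisymmetric_under_condition_swap(self, rng):
        x = rng.standard_normal(9)
        y = rng.standard_normal(9)
        a = s_statistic(make_series("s", "SYNC", x), make_series("s", "ASYNC", y))
        b = s_statistic(make_series("s", "SYNC", y), make_series("s", "ASYNC", x))
        assert a == pytest.approx(-b, abs=1e-10)

    def test_requires_correct_condition_order(self):
        s = make_series("s", "SYNC", np.arange(9.0))
        with pytest.raises(ValueError):
            s_statistic(s, s)


class TestPeakEnd:
    def test_constant_series(self):
        # constant stim values c after baseline subtraction: mean(max, last) = c
        sync = make_series("s", "SYNC", np.array([0, 0, 0.4, 0.4, 0, 0.0]))
        asyn = make_series("s", "ASYNC", np.array([0, 0, 0.1, 0.1, 0, 0.0]))
        assert peak_end_summary(sync, asyn) == pytest.approx(0.3)

    def test_monotone_series_equals_last(self):
        sync = make_series("s", "SYNC", np.array([0, 0, 0.1, 0.5, 0, 0.0]))
        asyn = make_series("s", "ASYNC", np.array([0, 0, 0.0, 0.0, 0, 0.0]))
        # sync: mean(max=0.5, last=0.5) = 0.5
        assert peak_end_summary(sync, asyn) == pytest.approx(0.5)

    def test_single_step_series(self):
        sync = make_series("s", "SYNC", np.array([0.0, 0.2, 0.0]))
        asyn = make_series("s", "ASYNC", np.array([0.0, 0.0, 0.0]))
        assert peak_end_summary(sync, asyn) == pytest.approx(0.2)


def _ratings_row(sid, cond, **q):
    row = {"subject_id": sid, "condition": cond}
    for i in range(1, 10):
        row[f"Q{i}"] = q.get(f"Q{i}", 50.0)
    return row


class TestRhiIndex:
    def test_neutral_ratings(self):
        df = pd.DataFrame([_ratings_row("a", "SYNC"), _ratings_row("a", "ASYNC")])
        out = rhi_index(df)
        assert out.rhi_sync.iloc[0] == 50.0 and out.rhi_diff.iloc[0] == 0.0

    def test_mean_of_first_three_items(self):
        df = pd.DataFrame([
            _ratings_row("a", "SYNC", Q1=90, Q2=60, Q3=90),
            _ratings_row("a", "ASYNC", Q1=30, Q2=30, Q3=30),
        ])
        out = rhi_index(df)
        assert out.rhi_sync.iloc[0] == pytest.approx(80.0)
        assert out.rhi_diff.iloc[0] == pytest.approx(50.0)
        assert out.dQ1.iloc[0] == 60.0
        # extended mean over dQ1, dQ2, dQ3, dQ7, dQ8
        assert out.extended_diff.iloc[0] == pytest.approx((60 + 30 + 60 + 0 + 0) / 5)

    def test_missing_item_errors(self):
        df = pd.DataFrame([_ratings_row("a", "SYNC"), _ratings_row("a", "ASYNC")])
        with pytest.raises(ValueError, match="Q5"):
            rhi_index(df.drop(columns=["Q5"]))

    def test_out_of_scale_errors(self):
        df = pd.DataFrame([_ratings_row("a", "SYNC", Q1=140), _ratings_row("a", "ASYNC")])
        with pytest.raises(ValueError):
            rhi_index(df)

    def test_missing_condition_errors(self):
        df = pd.DataFrame([_ratings_row("a", "SYNC")])
        with pytest.raises(ValueError, match="ASYNC"):
            rhi_index(df)


class TestCorrelate:
    def test_perfectly_linear_scores(self):
        df = pd.DataFrame({"s_phi": [1, 2, 3, 4.0], "rhi_diff": [10, 20, 30, 40.0]})
        r, n, p = correlate(df)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(7)
        reps, hits, n = 500, 0, 20
        crit = sps.t.ppf(0.975, n - 2)
        for _ in range(reps):
            df = pd.DataFrame({"s_phi": rng.standard_normal(n),
                               "rhi_diff": rng.standard_normal(n)})
            _, _, p = correlate(df)
            hits += p < 0.05
        rate = hits / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_too_few_subjects_errors(self):
        df = pd.DataFrame({"s_phi": [1.0, 2.0], "rhi_diff": [1.0, 2.0]})
        with pytest.raises(ValueError):
            correlate(df)


class TestPerSubjectContrast:
    def test_per_subject_means_reduce_to_one_value_each(self):
        rng = np.random.default_rng(3)
        series = {}
        for i in range(6):
            x = rng.standard_normal(90)
            x[30:60] -= 1.0
            series[f"s{i}"] = make_series(f"s{i}", "SYNC", x)
        pc = phase_contrast(series, "phi_mip", per_subject=True)
        assert pc.phase_counts == {"pre": 6, "stim": 6, "post": 6}
        row = pc.tests.set_index(["phase_a", "phase_b"]).loc[("pre", "stim")]
        assert row.t > 0 and row.df < 11
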