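"""Accuracy, dispersion, family, progress and aggregation statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from preselsim import metrics as mt
from preselsim import scheme as sc
from preselsim import traits as tr


class TestAccuracy:
    def test_perfect_and_anti_correlation(self):
        x = np.arange(10.0)
        assert mt.accuracy(x, x) == pytest.approx(1.0)
        assert mt.accuracy(x, -x) == pytest.approx(-1.0)

    def test_independent_draws_are_near_zero(self):
        rng = np.random.default_rng(0)
        r = mt.accuracy(rng.standard_normal(10_000), rng.standard_normal(10_000))
        assert abs(r) < 0.05

    def test_degenerate_inputs_reported_missing(self):
        assert np.isnan(mt.accuracy([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))
        assert np.isnan(mt.accuracy([1.0, 2.0], [1.0, 2.0]))


class TestDispersionRC:
    def test_identity_and_double_slope(self):
        x = np.arange(20.0)
        assert mt.dispersion_rc(x, x) == pytest.approx(1.0)
        assert mt.dispersion_rc(2 * x, x) == pytest.approx(2.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        gebv = rng.standard_normal(200)
        tbv = 0.8 * gebv + rng.standard_normal(200)
        want = (np.sum((tbv - tbv.mean()) * (gebv - gebv.mean()))
                / np.sum((gebv - gebv.mean()) ** 2))
        assert mt.dispersion_rc(tbv, gebv) == pytest.approx(want, abs=1e-12)

    def test_zero_gebv_variance_raises(self):
        with pytest.raises(ValueError):
            mt.dispersion_rc([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])

    @given(shift=st.floats(-5, 5), scale=st.floats(0.5, 2.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_location_invariant_and_inverse_scale_covariant(self, shift, scale):
        rng = np.random.default_rng(2)
        gebv = rng.standard_normal(50)
        tbv = gebv + 0.3 * rng.standard_normal(50)
        base = mt.dispersion_rc(tbv, gebv)
        assert mt.dispersion_rc(tbv, gebv + shift) == pytest.approx(base, rel=1e-9)
        assert mt.dispersion_rc(tbv, gebv * scale) == pytest.approx(base / scale,
                                                                    rel=1e-9)


class TestFamilyRepresentation:
    def test_single_and_distinct_families(self):
        dam_of = np.array([-1, -1, 1, 1, 1, 1])
        sex_of = np.array([False, False, True, True, False, False])
        out = mt.family_representation(np.array([2, 3, 4]), dam_of, sex_of)
        assert out == {"male": 1, "female": 1}
        dam_of2 = np.array([-1, -1, -1, 0, 1, 2])
        out2 = mt.family_representation(np.array([3, 4, 5]), dam_of2,
                                        np.array([False] * 3 + [True] * 3))
        assert out2 == {"male": 3, "female": 0}

    def test_matches_set_cardinality_oracle(self):
        rng = np.random.default_rng(3)
        dam_of = rng.integers(0, 15, 100)
        sex_of = rng.random(100) < 0.5
        sel = rng.choice(100, 30, replace=False)
        out = mt.family_representation(sel, dam_of, sex_of)
        assert out["male"] == len({dam_of[i] for i in sel if sex_of[i]})
        assert out["female"] == len({dam_of[i] for i in sel if not sex_of[i]})

    def test_unknown_dam_rejected(self):
        with pytest.raises(ValueError):
            mt.family_representation(np.array([0]), np.array([-1]),
                                     np.array([True]))


class TestProgress:
    @staticmethod
    def _log_with_means(mean_a, mean_b):
        """Minimal two-round log whose candidate means are fixed."""
        params = tr.TraitParams()
        config = sc.SchemeConfig(chicks_per_round=60, hatches_per_round=2,
                                 presel_male_frac=0.5, presel_female_frac=0.5,
                                 criterion="P", n_sires=1, n_dams=4,
                                 mates_per_sire=4,
                                 chicks_per_dam_by_stage=(4, 4, 4, 3),
                                 n_rounds=2)
        rounds = []
        for mean in (mean_a, mean_b):
            n = 10
            frame = pd.DataFrame({
                "id": np.arange(n), "sex": ["M", "F"] * 5,
                "dam": np.zeros(n, dtype=int),
                "preselected": [True] * n, "selected": [False] * n,
            })
            for i, t in enumerate(["bw", "rfi", "gain"]):
                vals = np.linspace(-1, 1, n) + mean[i]
                frame[f"tbv_{t}"] = vals * params.genetic_sd[i]
                frame[f"final_gebv_{t}"] = vals * params.genetic_sd[i]
            rounds.append(frame)
        return sc.SimulationLog(config=config, rounds=rounds), params

    def test_identical_means_give_zero(self):
        log, params = self._log_with_means([1, 1, 1], [1, 1, 1])
        out = mt.standardized_progress(log, params, "TBV", 1, 2)
        assert out["bw"] == pytest.approx(0.0, abs=1e-12)
        assert out["index"] == pytest.approx(0.0, abs=1e-12)

    def test_reported_delta_arithmetic(self):
        """Standardized means 5.93 -> 8.00 give a progress of 2.07 SD."""
        log, params = self._log_with_means([5.93, 0, 0], [8.00, 0, 0])
        out = mt.standardized_progress(log, params, "TBV", 1, 2)
        assert out["bw"] == pytest.approx(2.07, abs=1e-9)

    def test_rfi_decline_is_negative_progress(self):
        log, params = self._log_with_means([0, -2.0, 0], [0, -2.6, 0])
        out = mt.standardized_progress(log, params, "TBV", 1, 2)
        assert out["rfi"] == pytest.approx(-0.6, abs=1e-9)
        # and the index rewards it: -0.82 weight on a negative delta
        assert out["index"] == pytest.approx(0.82 * 0.6, abs=1e-9)

    def test_missing_round_rejected(self):
        log, params = self._log_with_means([0, 0, 0], [1, 1, 1])
        with pytest.raises(ValueError):
            mt.standardized_progress(log, params, "TBV", 1, 5)


class TestOverestimation:
    def test_equal_and_double(self):
        assert mt.progress_overestimation(2.0, 2.0) == 0.0
        assert mt.progress_overestimation(4.0, 2.0) == 100.0

    def test_reported_body_weight_case(self):
        """Delta_TBV 2.07 with GEBV excess 1.19 is a 57% overestimate."""
        assert round(mt.progress_overestimation(2.07 + 1.19, 2.07)) == 57

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError):
            mt.progress_overestimation(1.0, 0.0)


class TestReplicateSE:
    def test_constant_and_two_point_cases(self):
        assert mt.replicate_se([3.0, 3.0, 3.0]) == 0.0
        assert mt.replicate_se([0.0, 2.0]) == pytest.approx(1.0)
        assert np.isnan(mt.replicate_se([1.0]))

    def test_monte_carlo_mean_matches_theory(self):
        rng = np.random.default_rng(4)
        ses = [mt.replicate_se(rng.standard_normal(15)) for _ in range(10_000)]
        assert np.mean(ses) == pytest.approx(1 / np.sqrt(15), abs=0.01)


class TestCompareStrategies:
    def test_identical_samples_give_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert mt.compare_strategies(x, list(x)) == pytest.approx(1.0)

    def test_large_shift_is_detected(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal(15)
        assert mt.compare_strategies(a, a + 10.0) < 1e-3

    def test_matches_welch_formula(self):
        rng = np.random.default_rng(6)
        a, b = rng.standard_normal(12), 0.5 + rng.standard_normal(9)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
        from scipy import stats
        want = 2 * stats.t.sf(abs(t), df)
        assert mt.compare_strategies(a, b) == pytest.approx(want, rel=1e-9)


class TestSummarize:
    @staticmethod
    def _toy_logs(seed=0):
        rng = np.random.default_rng(seed)
        params = tr.TraitParams()
        config = sc.SchemeConfig(chicks_per_round=60, hatches_per_round=2,
                                 presel_male_frac=0.5, presel_female_frac=0.5,
                                 criterion="G", n_sires=1, n_dams=4,
                                 mates_per_sire=4,
                                 chicks_per_dam_by_stage=(4, 4, 4, 3),
                                 n_rounds=2)
        logs = []
        for _ in range(2):
            rounds = []
            for _ in range(2):
                n = 20
                tbv = rng.standard_normal((n, 3)) * params.genetic_sd
                gebv = 0.8 * tbv + 0.2 * rng.standard_normal((n, 3))
                frame = pd.DataFrame({
                    "id": np.arange(n), "sex": ["M", "F"] * 10,
                    "dam": rng.integers(0, 5, n),
                    "preselected": [True] * n,
                    "selected": [True] * 4 + [False] * (n - 4),
                })
                for i, t in enumerate(["bw", "rfi", "gain"]):
                    frame[f"tbv_{t}"] = tbv[:, i]
                    frame[f"presel_ebv_{t}"] = gebv[:, i]
                    frame[f"final_gebv_{t}"] = gebv[:, i]
                frame["presel_index"] = 0.0
                rounds.append(frame)
            logs.append(sc.SimulationLog(config=config, rounds=rounds))
        return logs, params

    def test_single_replicate_window_equals_raw_round_statistics(self):
        logs, params = self._toy_logs()
        summary = mt.summarize_strategy(logs[:1], params, window=(2, 2),
                                        progress_rounds=(1, 2))
        raw = mt.round_statistics(logs[0], 2)
        assert summary["rc_bw"] == pytest.approx(raw["rc_bw"])
        assert summary["final_accuracy_rfi"] == pytest.approx(
            raw["final_accuracy_rfi"])

    def test_permutation_of_replicates_is_invariant(self):
        logs, params = self._toy_logs()
        a = mt.summarize_strategy(logs, params, window=(1, 2),
                                  progress_rounds=(1, 2))
        b = mt.summarize_strategy(logs[::-1], params, window=(1, 2),
                                  progress_rounds=(1, 2))
        assert np.allclose(a.mean.to_numpy(), b.mean.to_numpy(),
                           equal_nan=True)
        assert np.allclose(a.se.to_numpy(), b.se.to_numpy(), equal_nan=True)

    def test_hand_computed_two_replicate_aggregation(self):
        logs, params = self._toy_logs()
        summary = mt.summarize_strategy(logs, params, window=(1, 2),
                                        progress_rounds=(1, 2))
        # spreadsheet-style oracle for the final BW accuracy
        per_rep = []
        for log in logs:
            accs = []
            for rnd in (1, 2):
                frame = log.round_frame(rnd)
                accs.append(np.corrcoef(frame["tbv_bw"],
                                        frame["final_gebv_bw"])[0, 1])
            per_rep.append(np.mean(accs))
        assert summary["final_accuracy_bw"] == pytest.approx(np.mean(per_rep))
        want_se = np.std(per_rep, ddof=1) / np.sqrt(2)
        assert summary.se["final_accuracy_bw"] == pytest.approx(want_se)

    def test_mixed_configurations_rejected(self):
        logs, params = self._toy_logs()
        logs[1].config = sc.SchemeConfig(criterion="P",
                                         presel_male_frac=0.10,
                                         presel_female_frac=0.30)
        with pytest.raises(ValueError):
            mt.summarize_strategy(logs, params, window=(1, 2),
                                  progress_rounds=(1, 2))
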