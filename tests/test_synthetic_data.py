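"""Synthetic cohort, series and trace generation with known ground truth."""

import numpy as np
import pandas as pd
import pytest

from fatkin import (
    COHORT_MEANS,
    COHORT_SDS,
    PARAM_COLUMNS,
    CohortConfig,
    TraceConfig,
    default_correlation,
    exp_decay,
    extract_nm_metrics,
    generate_cohort_parameters,
    generate_nm_trace,
    generate_observations,
    nearest_psd,
)


class TestCohortParameters:
    def test_row_count_equals_n_subjects(self):
        df = generate_cohort_parameters(CohortConfig(n_subjects=13, seed=0))
        assert df.shape == (13, 1 + 12)
        assert list(df.columns[1:]) == list(PARAM_COLUMNS)

    def test_zero_sds_give_exact_means(self):
        cfg = CohortConfig(n_subjects=5, sds={c: 0.0 for c in PARAM_COLUMNS}, seed=0)
        df = generate_cohort_parameters(cfg)
        for c in PARAM_COLUMNS:
            assert np.allclose(df[c], COHORT_MEANS[c])

    def test_configured_correlation_recovered_monte_carlo(self):
        cfg = CohortConfig(n_subjects=2000, seed=42)
        df = generate_cohort_parameters(cfg)
        r = np.corrcoef(df["A_VA_HF"], df["A_QTW_HF"])[0, 1]
        # the PSD repair shifts the nominal -0.70 slightly; compare to the
        # repaired matrix actually sampled from
        i = PARAM_COLUMNS.index("A_VA_HF")
        j = PARAM_COLUMNS.index("A_QTW_HF")
        target = cfg.correlation[i, j]
        assert r == pytest.approx(target, abs=0.05)
        assert r == pytest.approx(-0.70, abs=0.08)

    def test_means_and_sds_recovered_within_3_se(self):
        n = 2000
        df = generate_cohort_parameters(CohortConfig(n_subjects=n, seed=7))
        for c in ("A_IMVC_HF", "tau_VA_LF", "A_QTW_LF"):
            se = COHORT_SDS[c] / np.sqrt(n)
            # truncation to (0,100]/(0,inf) can bias slightly; 3 SE plus a
            # small truncation allowance
            assert abs(df[c].mean() - COHORT_MEANS[c]) < 3 * se + 0.5
            assert df[c].std(ddof=1) == pytest.approx(COHORT_SDS[c], rel=0.1)

    def test_physical_ranges_enforced(self):
        df = generate_cohort_parameters(CohortConfig(n_subjects=500, seed=1))
        for c in PARAM_COLUMNS:
            if c.startswith("A_"):
                assert ((df[c] > 0) & (df[c] <= 100)).all()
            else:
                assert (df[c] > 0).all()

    def test_same_seed_bit_identical(self):
        a = generate_cohort_parameters(CohortConfig(seed=9))
        b = generate_cohort_parameters(CohortConfig(seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            CohortConfig(n_subjects=1)

    def test_negative_sd_rejected(self):
        sds = dict(COHORT_SDS)
        sds["A_VA_HF"] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            CohortConfig(sds=sds)


class TestNearestPsd:
    def test_psd_matrix_returned_unchanged(self):
        R = np.eye(3)
        assert np.array_equal(nearest_psd(R), R)

    def test_default_correlation_repaired_to_psd(self):
        repaired = nearest_psd(default_correlation())
        w = np.linalg.eigvalsh(repaired)
        assert w.min() >= -1e-10
        assert np.allclose(np.diag(repaired), 1.0)

    def test_structurally_invalid_matrix_rejected(self):
        R = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            nearest_psd(R, repair_tol=0.15)

    def test_asymmetric_rejected(self):
        R = np.eye(2)
        R[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            nearest_psd(R)


class TestObservations:
    def test_noiseless_equals_model_to_machine_precision(self):
        truth = pd.DataFrame([{"subject_id": "01", **{c: COHORT_MEANS[c] for c in PARAM_COLUMNS}}])
        times = np.arange(0.0, 161.0, 20.0)
        series = generate_observations(truth, times, noise_sd=0.0, seed=0)
        assert len(series) == 6
        for s in series:
            a = truth.iloc[0][f"A_{s.variable}_{s.condition}"]
            tau = truth.iloc[0][f"tau_{s.variable}_{s.condition}"]
            assert np.allclose(s.values, exp_decay(times, a, tau), atol=1e-12)

    def test_hand_evaluated_point(self):
        truth = pd.DataFrame([{"subject_id": "01", **{c: COHORT_MEANS[c] for c in PARAM_COLUMNS}}])
        truth["A_IMVC_HF"], truth["tau_IMVC_HF"] = 64.0, 31.0
        s = [x for x in generate_observations(truth, noise_sd=0.0)
             if x.condition == "HF" and x.variable == "IMVC"][0]
        assert s.values[1] == pytest.approx(64 + 36 * np.exp(-20 / 31))
        assert s.values[1] == pytest.approx(82.9, abs=0.05)

    def test_baseline_point_exactly_100_even_with_noise(self):
        truth = pd.DataFrame([{"subject_id": "01", **{c: COHORT_MEANS[c] for c in PARAM_COLUMNS}}])
        for s in generate_observations(truth, noise_sd=5.0, seed=3):
            assert s.values[0] == 100.0

    def test_no_fatigue_limit_gives_constant_100(self):
        truth = pd.DataFrame([{"subject_id": "01",
                               **{c: (100.0 if c.startswith("A_") else 30.0)
                                  for c in PARAM_COLUMNS}}])
        for s in generate_observations(truth, noise_sd=0.0):
            assert np.allclose(s.values, 100.0)

    def test_negative_noise_rejected(self):
        truth = pd.DataFrame([{"subject_id": "01", **{c: COHORT_MEANS[c] for c in PARAM_COLUMNS}}])
        with pytest.raises(ValueError, match="non-negative"):
            generate_observations(truth, noise_sd=-1.0)

    def test_same_seed_bit_identical(self):
        truth = generate_cohort_parameters(CohortConfig(seed=5))
        a = generate_observations(truth, noise_sd=3.0, seed=5)
        b = generate_observations(truth, noise_sd=3.0, seed=5)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.values, s2.values)


class TestTraceGeneration:
    def test_twitch_shape_peaks_at_tc_with_amp(self):
        # f(s) = amp * (s/Tc) * exp(1 - s/Tc) has maximum amp at s = Tc
        from fatkin.synthetic_data import _twitch
        tc, amp = 0.06, 10.0
        s = np.linspace(0, 0.5, 20001)
        f = _twitch(s, 0.0, amp, tc)
        assert f.max() == pytest.approx(amp, rel=1e-6)
        assert s[np.argmax(f)] == pytest.approx(tc, abs=1e-3)

    def test_ground_truth_va_hand_example(self):
        _, truth = generate_nm_trace(
            TraceConfig(plateau_torque=250.0, twitch_amplitude=10.0,
                        resting_twitch_amplitude=96.0)
        )
        # VA = (1 - 10 * (250/250) / 96) * 100
        assert truth.VA == pytest.approx((1 - 10 / 96) * 100)
        assert truth.VA == pytest.approx(89.58, abs=0.01)

    def test_noiseless_roundtrip_recovers_ground_truth(self, nm_trace):
        trace, truth = nm_trace
        m = extract_nm_metrics(trace)
        for attr in ("T_max", "T_stim", "ST", "Q_tw", "imvc_plateau", "VA"):
            assert getattr(m, attr) == pytest.approx(getattr(truth, attr), rel=5e-3)

    def test_stimulus_ordering_validated(self):
        with pytest.raises(ValueError, match="increasing"):
            TraceConfig(stim_times=(4.5, 2.5))
        with pytest.raises(ValueError, match="overlap"):
            TraceConfig(stim_times=(2.5, 2.6))

    def test_same_seed_bit_identical(self):
        t1, _ = generate_nm_trace(TraceConfig(baseline_noise_sd=1.0, seed=4))
        t2, _ = generate_nm_trace(TraceConfig(baseline_noise_sd=1.0, seed=4))
        assert np.array_equal(t1.torque, t2.torque)
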