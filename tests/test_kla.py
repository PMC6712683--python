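import numpy as np
import pytest

from oursoft.errors import DataError, DomainError, FitError, InsufficientDataError
from oursoft.kla import (
    DOStepResponse,
    KlaModel,
    estimate_kla,
    fit_kla_model,
    predict_kla,
    probe_response_valid,
)
from oursoft.synthetic import generate_characterization, simulate_gassing_step

PROBE_FLIP_KLA = 3600.0 / 49.6  # h^-1 where tau_p = 1/kLa


class TestEstimateKla:
    @pytest.mark.parametrize("kla_true", [1.0, 5.0, 10.0, 50.0])
    def test_noise_free_recovery(self, kla_true):
        est = estimate_kla(simulate_gassing_step(kla_true))
        assert est.kla == pytest.approx(kla_true, rel=1e-3)

    def test_gassing_directions_agree(self):
        est_in = estimate_kla(simulate_gassing_step(10.0, direction="in"))
        est_out = estimate_kla(simulate_gassing_step(10.0, direction="out"))
        assert est_in.kla == pytest.approx(est_out.kla, rel=1e-9)

    def test_affine_rescaling_of_do_axis(self):
        # the 20-80 % window is relative to the response span
        step = simulate_gassing_step(8.0)
        rescaled = DOStepResponse(
            times=step.times, do_pct=0.6 * step.do_pct + 15.0,
            direction=step.direction, tau_p=step.tau_p,
        )
        assert estimate_kla(rescaled).kla == pytest.approx(
            estimate_kla(step).kla, rel=1e-9
        )

    def test_validity_flag_slow_transfer(self):
        assert estimate_kla(simulate_gassing_step(10.0)).valid

    def test_validity_flag_fast_transfer(self):
        # 80 h^-1 > 1/tau_p: probe lag no longer negligible
        assert not estimate_kla(simulate_gassing_step(80.0)).valid

    def test_constant_trace_rejected(self):
        step = DOStepResponse(times=np.linspace(0, 100, 50),
                              do_pct=np.full(50, 55.0))
        with pytest.raises(DataError, match="constant DO"):
            estimate_kla(step)

    def test_too_few_window_points_rejected(self):
        step = simulate_gassing_step(10.0, n_samples=8)
        with pytest.raises(InsufficientDataError):
            estimate_kla(step)

    def test_non_monotone_time_rejected(self):
        with pytest.raises(DataError, match="strictly increasing"):
            DOStepResponse(times=np.array([0.0, 2.0, 1.0, 3.0, 4.0]),
                           do_pct=np.linspace(0, 80, 5))

    def test_noisy_estimates_unbiased(self):
        kla_true = 10.0
        errors = [
            estimate_kla(simulate_gassing_step(kla_true, noise_sd=0.5, seed=s)).kla
            - kla_true
            for s in range(200)
        ]
        errors = np.asarray(errors)
        mc_err = errors.std(ddof=1) / np.sqrt(errors.size)
        assert abs(errors.mean()) < 4 * mc_err + 1e-3 * kla_true


class TestProbeValidity:
    def test_flips_at_inverse_probe_constant(self):
        assert probe_response_valid(PROBE_FLIP_KLA * 0.999, 49.6)
        assert not probe_response_valid(PROBE_FLIP_KLA * 1.001, 49.6)

    def test_requires_positive_kla(self):
        with pytest.raises(DomainError):
            probe_response_valid(0.0)


class TestKlaModelFit:
    def test_exact_plane_recovered(self):
        rng = np.random.default_rng(7)
        t = rng.uniform(303, 311, 12)
        pid = rng.uniform(0, 60, 12)
        kla = -40.0 + 0.2 * pid + 0.14 * t
        model = fit_kla_model(t, pid, kla)
        assert model.coefficients() == pytest.approx([-40.0, 0.2, 0.14], abs=1e-9)

    def test_noisy_recovery_within_3_se(self):
        rng = np.random.default_rng(11)
        t = rng.uniform(303, 311, 30)
        pid = rng.uniform(0, 60, 30)
        truth = np.array([-40.0, 0.2, 0.14])
        kla = truth[0] + truth[1] * pid + truth[2] * t
        noisy = kla + rng.normal(0, 0.02 * np.ptp(kla), kla.size)
        model = fit_kla_model(t, pid, noisy)
        for est, true, se in zip(model.coefficients(), truth, model.stderr):
            assert abs(est - true) < 3 * se

    def test_rank_deficient_design_rejected(self):
        t = np.full(6, 310.15)
        pid = np.full(6, 30.0)
        with pytest.raises(FitError, match="rank-deficient|collinear"):
            fit_kla_model(t, pid, np.arange(6.0))

    def test_medium_transfers_faster_than_water(self):
        # medium components suppress coalescence: kLa several-fold higher
        from oursoft.solubility import celsius_to_kelvin

        fits = {}
        for liquid in ("medium", "water"):
            df = generate_characterization(liquid=liquid, seed=3)
            fits[liquid] = fit_kla_model(
                celsius_to_kelvin(df["temp_C"].to_numpy()),
                df["pid_pct"].to_numpy(),
                df["kla_h"].to_numpy(),
                liquid=liquid,
            )
        t_k, pid = 310.15, 30.0
        assert (
            predict_kla(fits["medium"], t_k, pid).kla
            > 3 * predict_kla(fits["water"], t_k, pid).kla
        )


class TestPredictKla:
    MODEL = KlaModel(beta0=0.0, beta_pid=0.1, beta_t=0.0,
                     fitted_pid_max=60.0, fitted_t_range=(300.0, 315.0))

    def test_plane_arithmetic(self):
        pred = predict_kla(self.MODEL, 310.0, 50.0)
        assert pred.kla == pytest.approx(5.0)
        assert not pred.extrapolated

    def test_extrapolation_above_fitted_pid(self):
        pred = predict_kla(self.MODEL, 310.0, 70.0)
        assert pred.kla == pytest.approx(7.0)
        assert pred.extrapolated

    def test_round_trip_on_training_grid(self):
        rng = np.random.default_rng(5)
        t = rng.uniform(304, 311, 9)
        pid = rng.uniform(5, 55, 9)
        kla = 2.0 + 0.15 * pid + 0.01 * t
        model = fit_kla_model(t, pid, kla)
        for ti, pi, ki in zip(t, pid, kla):
            assert predict_kla(model, ti, pi).kla == pytest.approx(ki, rel=1e-9)

    def test_negative_prediction_rejected(self):
        model = KlaModel(beta0=-100.0, beta_pid=0.1, beta_t=0.0)
        with pytest.raises(DomainError, match="negative kLa"):
            predict_kla(model, 310.0, 10.0)

    def test_pid_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            predict_kla(self.MODEL, 310.0, 101.0)


class TestRecoveryUnbiased:
    def test_plane_fit_unbiased_over_replicates(self):
        """Mean coefficient error over 200 seeded replicates is within
        Monte-Carlo error of zero."""
        truth = np.array([-40.0, 0.2, 0.14])
        rng = np.random.default_rng(2024)
        t = rng.uniform(303, 311, 18)
        pid = rng.uniform(0, 60, 18)
        clean = truth[0] + truth[1] * pid + truth[2] * t
        errs = np.empty((200, 3))
        for i in range(200):
            noisy = clean + rng.normal(0, 0.02 * np.ptp(clean), clean.size)
            errs[i] = fit_kla_model(t, pid, noisy).coefficients() - truth
        mc = errs.std(axis=0, ddof=1) / np.sqrt(errs.shape[0])
        assert np.all(np.abs(errs.mean(axis=0)) < 4 * mc)
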