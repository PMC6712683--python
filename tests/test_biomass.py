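import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oursoft.biomass import (
    CapacitanceModel,
    SegmentedLinearModel,
    filter_viable,
    fit_capacitance,
    fit_segmented,
    line_intersection,
    mape,
    predict_pcv_from_capacitance,
    predict_pcv_from_our,
    train_test_mape,
)
from oursoft.errors import DataError, DomainError, FitError


def kinked(x, k1=2.52, d1=-0.66, k2=0.06, x_break=1.4):
    d2 = (k1 - k2) * x_break + d1
    return np.where(x <= x_break, k1 * x + d1, k2 * x + d2)


class TestFilterViable:
    def test_all_viable_identity(self):
        df = pd.DataFrame({"viability": [90.0, 92.0], "pcv": [1.0, 2.0]})
        pd.testing.assert_frame_equal(filter_viable(df), df)

    def test_boundary_inclusive_at_80(self):
        df = pd.DataFrame({"viability": [85.0, 79.9, 80.0]})
        kept = filter_viable(df)
        assert list(kept.index) == [0, 2]

    def test_empty_result_warns(self):
        df = pd.DataFrame({"viability": [10.0, 20.0]})
        with pytest.warns(UserWarning, match="below 80"):
            out = filter_viable(df)
        assert out.empty

    def test_missing_column_rejected(self):
        with pytest.raises(DataError):
            filter_viable(pd.DataFrame({"pcv": [1.0]}))


class TestFitSegmented:
    @pytest.mark.parametrize("x_break", [0.9, 1.4, 2.0])
    def test_noise_free_breakpoint_exact(self, x_break):
        x = np.linspace(0.3, 3.2, 80)
        model = fit_segmented(x, kinked(x, x_break=x_break))
        assert model.x_break == pytest.approx(x_break, abs=1e-6)

    def test_noise_free_coefficients_exact(self):
        x = np.linspace(0.3, 3.2, 80)
        model = fit_segmented(x, kinked(x))
        assert model.k1 == pytest.approx(2.52, abs=1e-9)
        assert model.d1 == pytest.approx(-0.66, abs=1e-9)
        assert model.k2 == pytest.approx(0.06, abs=1e-9)

    def test_printed_coefficients_intersection(self):
        # rounded published coefficients meet at (0.032+0.011)/(0.042-0.001)
        assert line_intersection(0.042, -0.011, 0.001, 0.032) == pytest.approx(
            1.048780487804878, abs=1e-9
        )

    def test_single_global_line_degenerate(self):
        x = np.linspace(0.0, 4.0, 40)
        with pytest.raises(FitError):
            fit_segmented(x, 2.0 * x + 1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(DataError):
            fit_segmented(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))

    def test_equivariance_y_affine_x_translation(self):
        rng = np.random.default_rng(42)
        x = np.sort(rng.uniform(0.3, 3.2, 90))
        y = kinked(x) + rng.normal(0, 0.05, x.size)
        base = fit_segmented(x, y)
        scaled = fit_segmented(x, 3.5 * y - 2.0)
        assert scaled.x_break == pytest.approx(base.x_break, abs=1e-5)
        shifted = fit_segmented(x + 10.0, y)
        assert shifted.x_break == pytest.approx(base.x_break + 10.0, abs=1e-5)

    def test_breakpoint_recovery_under_noise(self):
        """Median |breakpoint error| < 5 % of the x-range with 10 %-of-range
        noise, n = 60, over 200 seeded replicates."""
        x = np.linspace(0.3, 3.2, 60)
        clean = kinked(x)
        sd = 0.10 * np.ptp(clean)
        errs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            try:
                model = fit_segmented(x, clean + rng.normal(0, sd, x.size))
                errs.append(abs(model.x_break - 1.4))
            except FitError:
                errs.append(np.inf)
        assert np.median(errs) < 0.05 * np.ptp(x)


class TestPredictFromOur:
    MODEL = SegmentedLinearModel(k1=2.0, d1=0.0, k2=0.5, d2=2.1, x_break=1.4)

    def test_inverse_of_line(self):
        pcv, neg = predict_pcv_from_our(self.MODEL, 4.0, state=0)
        assert pcv == pytest.approx(2.0)
        assert not neg

    def test_breakpoint_is_fixed_point(self):
        our_at_break = self.MODEL.our_at(self.MODEL.x_break, state=0)
        pcv, _ = predict_pcv_from_our(self.MODEL, our_at_break, state=0)
        assert pcv == pytest.approx(self.MODEL.x_break)

    @pytest.mark.parametrize("state", [0, 1])
    def test_round_trip_per_segment(self, state):
        for pcv in (0.5, 1.4, 2.8):
            our = self.MODEL.our_at(pcv, state=state)
            back, _ = predict_pcv_from_our(self.MODEL, our, state=state)
            assert back == pytest.approx(pcv, rel=1e-12)

    def test_negative_result_flagged(self):
        _, neg = predict_pcv_from_our(self.MODEL, -1.0, state=0)
        assert neg

    def test_zero_slope_rejected(self):
        model = SegmentedLinearModel(k1=0.0, d1=1.0, k2=1.0, d2=0.0, x_break=1.0)
        with pytest.raises(FitError, match="zero slope"):
            predict_pcv_from_our(model, 2.0, state=0)


class TestFitCapacitance:
    def test_noise_free_simple_regression_exact(self):
        eps = np.linspace(0.0, 8.0, 20)
        pcv = 0.4 * eps + 0.1
        with pytest.warns(UserWarning, match="gamma"):
            model = fit_capacitance(eps, np.full_like(eps, 11.0), pcv,
                                    conductivity_ref=11.0)
        assert model.cell_factor == pytest.approx(0.4, abs=1e-9)
        assert model.offset == pytest.approx(0.1, abs=1e-9)
        assert model.gamma == 0.0

    def test_constant_conductivity_warns_and_fixes_gamma(self):
        eps = np.linspace(0.0, 8.0, 20)
        with pytest.warns(UserWarning, match="gamma"):
            model = fit_capacitance(eps, np.full_like(eps, 11.0), 0.4 * eps,
                                    conductivity_ref=11.0)
        assert model.gamma == 0.0

    def test_constant_permittivity_rejected(self):
        with pytest.raises(FitError, match="permittivity"):
            fit_capacitance(np.full(10, 3.0), np.linspace(10, 12, 10),
                            np.linspace(0, 2, 10))

    def test_known_parameters_recovered_within_3_se(self):
        cf, off, gamma, ref = 0.4, 0.05, 0.05, 11.0
        rng = np.random.default_rng(17)
        pcv = np.linspace(0.1, 3.2, 120)
        cond = ref + rng.uniform(-1.2, 1.2, pcv.size)
        eps = (pcv - off) / cf + gamma * (cond - ref)
        pcv_obs = pcv + rng.normal(0, 0.03, pcv.size)
        model = fit_capacitance(eps, cond, pcv_obs, conductivity_ref=ref)
        assert abs(model.cell_factor - cf) < 3 * model.stderr["cell_factor"]
        assert abs(model.gamma - gamma) < 3 * model.stderr["gamma"]

    def test_simulator_truth_recovered(self, noisy_dynamic_run):
        run = noisy_dynamic_run
        truth = run.truth.capacitance_model
        model = fit_capacitance(
            run.online["permittivity_pFcm"].to_numpy(),
            run.online["conductivity_mScm"].to_numpy(),
            run.truth.pcv_viable,
            conductivity_ref=truth.conductivity_ref,
        )
        assert abs(model.cell_factor - truth.cell_factor) < 3 * model.stderr["cell_factor"]
        assert abs(model.gamma - truth.gamma) < 3 * model.stderr["gamma"]


class TestPredictFromCapacitance:
    MODEL = CapacitanceModel(cell_factor=0.4, offset=0.0, gamma=0.05,
                             conductivity_ref=11.0)

    def test_zero_permittivity_zero_offset(self):
        assert predict_pcv_from_capacitance(self.MODEL, 0.0, 11.0) == 0.0

    def test_inverse_consistency_noise_free(self):
        eps = np.linspace(0.5, 8.0, 15)
        cond = np.linspace(10.5, 11.5, 15)
        pcv = self.MODEL.cell_factor * (
            eps - self.MODEL.gamma * (cond - self.MODEL.conductivity_ref)
        )
        np.testing.assert_allclose(
            predict_pcv_from_capacitance(self.MODEL, eps, cond), pcv, rtol=1e-12
        )

    def test_conductivity_shift_compensated(self):
        # adding gamma*delta to permittivity cancels a conductivity shift delta
        delta = 0.8
        base = predict_pcv_from_capacitance(self.MODEL, 5.0, 11.0)
        moved = predict_pcv_from_capacitance(
            self.MODEL, 5.0 + self.MODEL.gamma * delta, 11.0 + delta
        )
        assert moved == pytest.approx(base, rel=1e-12)


class TestMape:
    def test_perfect_prediction(self):
        assert mape(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0

    def test_fifty_percent(self):
        assert mape(np.array([2.0, 4.0]), np.array([1.0, 2.0])) == pytest.approx(50.0)

    def test_single_pair(self):
        assert mape(np.array([10.0]), np.array([11.0])) == pytest.approx(10.0)

    def test_zero_actual_rejected(self):
        with pytest.raises(DomainError):
            mape(np.array([0.0, 1.0]), np.array([1.0, 1.0]))

    def test_zero_iff_equal(self):
        a = np.array([1.5, 2.5, 3.5])
        assert mape(a, a * 1.001) > 0.0

    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, scale):
        a = np.array([1.0, 2.0, 4.0])
        p = np.array([1.1, 1.8, 4.4])
        assert mape(a * scale, p * scale) == pytest.approx(mape(a, p), rel=1e-9)


class TestTrainTestSplit:
    def test_split_semantics(self):
        df = pd.DataFrame(
            {
                "run": [1, 1, 2, 10, 10],
                "pcv_viable": [1.0, 2.0, 4.0, 2.0, 4.0],
                "pcv_predicted": [1.1, 2.2, 4.0, 1.0, 2.0],
            }
        )
        out = train_test_mape(df, test_runs=[10])
        assert out["training"] == pytest.approx(mape(
            np.array([1.0, 2.0, 4.0]), np.array([1.1, 2.2, 4.0])))
        assert out["test"] == pytest.approx(50.0)
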