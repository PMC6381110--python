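"""Parameter recovery, condition comparison and plateau checks."""

import numpy as np
import pytest

from sterolex.fitting import (
    VelocityDataset,
    compare_conditions,
    fit_velocity_model,
    plateau_check,
)
from sterolex.kinetics import VelocityModelParams, v0_hyperbolic, v0_quadratic
from sterolex.signals import FluorescenceTrace
from sterolex.synth import NoiseModel, generate_velocity_dataset

GRID = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0)
BASAL = VelocityModelParams(0.8, 0.05, 2.0, "basal")
STIM = VelocityModelParams(0.4, 0.1, 2.0, "plus_PIP")


class TestFitVelocityModel:
    @pytest.mark.parametrize("model", ["quadratic", "hyperbolic"])
    def test_noiseless_self_consistency(self, model):
        fn = v0_quadratic if model == "quadratic" else v0_hyperbolic
        o = np.array(GRID)
        data = VelocityDataset(o, fn(BASAL, o), np.zeros(o.size, int), BASAL.L0)
        result = fit_velocity_model(data, model)
        assert result.converged
        assert result.K1_hat == pytest.approx(BASAL.K1, rel=1e-3)
        assert result.k_plus2_hat == pytest.approx(BASAL.k_plus2, rel=1e-3)

    def test_noisy_recovery_hyperbolic(self):
        # 5% multiplicative noise, 3 replicates; the 15% band is the
        # ~97th percentile of the 200-repeat error distribution
        rng = np.random.default_rng(1)
        o = np.tile(GRID, 3)
        v = v0_hyperbolic(BASAL, o) * (1 + rng.normal(0, 0.05, o.size))
        data = VelocityDataset(o, v, np.repeat(np.arange(3), len(GRID)), BASAL.L0)
        result = fit_velocity_model(data, "hyperbolic")
        assert result.K1_hat == pytest.approx(BASAL.K1, rel=0.15)
        assert result.k_plus2_hat == pytest.approx(BASAL.k_plus2, rel=0.15)

    def test_noisy_recovery_quadratic(self):
        # K1 is intrinsically harder for the tight-binding form at these
        # conditions (CRLB σ ≈ 18% relative); 40% is the ~97th percentile
        # of the 200-repeat Monte-Carlo error distribution
        data = generate_velocity_dataset(BASAL, GRID, 3, NoiseModel(0.05, 0, 1))
        result = fit_velocity_model(data, "quadratic")
        assert result.K1_hat == pytest.approx(BASAL.K1, rel=0.40)
        assert result.k_plus2_hat == pytest.approx(BASAL.k_plus2, rel=0.15)

    def test_all_zero_data_flagged_degenerate(self):
        o = np.array(GRID)
        data = VelocityDataset(o, np.zeros(o.size), np.zeros(o.size, int), 2.0)
        result = fit_velocity_model(data, "quadratic")
        assert result.degenerate
        assert result.k_plus2_hat == pytest.approx(0.0, abs=1e-6)

    def test_permutation_invariance(self):
        data = generate_velocity_dataset(BASAL, GRID, 3, NoiseModel(0.05, 0, 7))
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(data))
        shuffled = VelocityDataset(
            data.o_total[perm], data.v0[perm], data.replicate[perm], data.L0
        )
        r1 = fit_velocity_model(data, "quadratic")
        r2 = fit_velocity_model(shuffled, "quadratic")
        assert r2.K1_hat == pytest.approx(r1.K1_hat, rel=1e-6)
        assert r2.k_plus2_hat == pytest.approx(r1.k_plus2_hat, rel=1e-6)

    def test_nested_limit_quadratic_fits_hyperbolic_data(self):
        # the hyperbolic form in o_total is valid when little protein is
        # bound (L0 ≪ K1); on such data, with the grid spanning K1, the
        # quadratic fit lands on an equivalent parameterisation
        # (K1_quad ≈ K1 − L0) and returns a compatible k+2
        p = VelocityModelParams(5.0, 0.05, 0.25)
        o = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 40.0])
        data = VelocityDataset(o, v0_hyperbolic(p, o), np.zeros(o.size, int), p.L0)
        result = fit_velocity_model(data, "quadratic")
        assert result.k_plus2_hat == pytest.approx(p.k_plus2, rel=0.05)
        assert result.K1_hat == pytest.approx(p.K1 - p.L0, rel=0.05)

    def test_too_few_distinct_concentrations_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            VelocityDataset(
                np.array([1.0, 1.0, 2.0, 2.0]),
                np.array([0.1, 0.1, 0.2, 0.2]),
                np.zeros(4, int),
                2.0,
            )


class TestCompareConditions:
    def _fit(self, params, seed):
        data = generate_velocity_dataset(params, GRID, 3, NoiseModel(0.05, 0, seed))
        return fit_velocity_model(data, "quadratic")

    def test_identical_fits_unit_folds(self):
        fit = self._fit(BASAL, 3)
        cmp_ = compare_conditions(fit, fit)
        assert cmp_.K1_fold == pytest.approx(1.0)
        assert cmp_.k_plus2_fold == pytest.approx(1.0)
        assert cmp_.second_order_fold == pytest.approx(1.0)

    def test_forced_fourfold_arithmetic(self):
        basal = self._fit(BASAL, 3)
        # halve K1 and double k+2 by construction
        from dataclasses import replace

        stim = replace(
            basal,
            K1_hat=basal.K1_hat / 2,
            k_plus2_hat=basal.k_plus2_hat * 2,
            condition="plus_PIP",
        )
        cmp_ = compare_conditions(basal, stim)
        assert cmp_.second_order_fold == pytest.approx(4.0)

    def test_synthetic_conditions_fold_in_band(self):
        # median over seeded dataset pairs: K1 halves, k+2 doubles → ~4-fold
        folds = []
        for i in range(20):
            cmp_ = compare_conditions(
                self._fit(BASAL, 100 + 2 * i), self._fit(STIM, 101 + 2 * i)
            )
            folds.append(cmp_.second_order_fold)
        assert 3.0 <= float(np.median(folds)) <= 5.0

    def test_unconverged_input_rejected(self):
        fit = self._fit(BASAL, 3)
        from dataclasses import replace

        bad = replace(fit, converged=False)
        with pytest.raises(ValueError, match="converge"):
            compare_conditions(bad, fit)


class TestPlateauCheck:
    def _trace(self, A, rate, t_end=600.0):
        t = np.linspace(0, t_end, 601)
        return FluorescenceTrace(t, A * (1 - np.exp(-rate * t)))

    def test_equal_asymptotes_ratio_one(self):
        report = plateau_check(self._trace(1.5, 0.05), self._trace(1.5, 0.2))
        assert report.basal_plateaued and report.stim_plateaued
        assert report.ratio == pytest.approx(1.0, rel=1e-3)

    def test_five_percent_higher_asymptote(self):
        report = plateau_check(self._trace(1.0, 0.05), self._trace(1.05, 0.05))
        assert report.ratio == pytest.approx(1.05, rel=1e-3)

    def test_non_plateauing_trace_flagged(self):
        t = np.linspace(0, 600, 601)
        ramp = FluorescenceTrace(t, 0.01 * t)
        report = plateau_check(ramp, self._trace(1.0, 0.05))
        assert not report.basal_plateaued
        assert report.ratio is None
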