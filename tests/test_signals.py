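"""Fluorescence conversions and initial-velocity extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sterolex.signals import (
    FluorescenceCalibration,
    FluorescenceTrace,
    background_subtract,
    binding_percent,
    dhe_transport_amount,
    fold_stimulation,
    initial_velocity,
    normalized_ratio,
    pip_transport_amount,
)


@pytest.fixture
def binding_cal():
    return FluorescenceCalibration(f0=100.0, fref=1000.0, accessible_ligand=10.0,
                                   assay_kind="dhe_binding")


@pytest.fixture
def transport_cal():
    return FluorescenceCalibration(f0=100.0, fref=1000.0, accessible_ligand=10.0,
                                   assay_kind="dhe_transport")


@pytest.fixture
def pip_cal():
    # fref is the full-equilibration control F_eq
    return FluorescenceCalibration(f0=100.0, fref=700.0, accessible_ligand=4.0,
                                   assay_kind="pip_transport")


class TestNormalizedRatio:
    def test_anchors_and_midpoint(self, binding_cal):
        assert normalized_ratio(binding_cal.fref, binding_cal) == 1.0
        assert normalized_ratio(binding_cal.f0, binding_cal) == 0.0
        mid = 0.5 * (binding_cal.f0 + binding_cal.fref)
        assert normalized_ratio(mid, binding_cal) == pytest.approx(0.5)

    def test_degenerate_calibration_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            FluorescenceCalibration(5.0, 5.0, 10.0, "dhe_binding")

    def test_clip_option(self, binding_cal):
        assert normalized_ratio(2000.0, binding_cal) > 1.0
        assert normalized_ratio(2000.0, binding_cal, clip=True) == 1.0


class TestBindingPercent:
    def test_complete_binding_at_floor(self, binding_cal):
        # F0 is the cyclodextrin control: all sterol off the liposome
        assert binding_percent(binding_cal.f0, binding_cal) == 100.0
        assert binding_percent(binding_cal.fref, binding_cal) == 0.0

    def test_eighty_percent_bound(self, binding_cal):
        f = binding_cal.f0 + 0.2 * (binding_cal.fref - binding_cal.f0)
        assert binding_percent(f, binding_cal) == pytest.approx(80.0)

    @given(frac=st.floats(-0.2, 1.2))
    @settings(max_examples=50, deadline=None)
    def test_percent_plus_ratio_conserved(self, frac):
        cal = FluorescenceCalibration(100.0, 1000.0, 10.0, "dhe_binding")
        f = cal.f0 + frac * (cal.fref - cal.f0)
        total = binding_percent(f, cal) + 100.0 * normalized_ratio(f, cal)
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_wrong_assay_kind_rejected(self, transport_cal):
        with pytest.raises(ValueError, match="binding"):
            binding_percent(500.0, transport_cal)


class TestDheTransportAmount:
    def test_anchors(self, transport_cal):
        assert dhe_transport_amount(transport_cal.f0, transport_cal) == 10.0
        assert dhe_transport_amount(transport_cal.fref, transport_cal) == 0.0
        mid = 0.5 * (transport_cal.f0 + transport_cal.fref)
        assert dhe_transport_amount(mid, transport_cal) == pytest.approx(5.0)

    def test_as_printed_is_complement(self, transport_cal):
        f = transport_cal.f0 + 0.3 * (transport_cal.fref - transport_cal.f0)
        default = dhe_transport_amount(f, transport_cal)
        printed = dhe_transport_amount(f, transport_cal, as_printed=True)
        assert default + printed == pytest.approx(transport_cal.accessible_ligand)

    @given(frac=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_transferred_plus_remaining_is_total(self, frac):
        cal = FluorescenceCalibration(100.0, 1000.0, 10.0, "dhe_transport")
        f = cal.f0 + frac * (cal.fref - cal.f0)
        transferred = dhe_transport_amount(f, cal)
        remaining = cal.accessible_ligand * normalized_ratio(f, cal)
        assert transferred + remaining == pytest.approx(
            cal.accessible_ligand, abs=1e-9
        )


class TestPipTransportAmount:
    def test_no_signal_no_transport(self, pip_cal):
        assert pip_transport_amount(pip_cal.f0, pip_cal) == 0.0

    def test_equilibration_control_is_half_pool(self, pip_cal):
        # at F_eq the ligand is split evenly between donor and acceptor
        assert pip_transport_amount(pip_cal.fref, pip_cal) == pytest.approx(2.0)

    def test_half_signal_is_quarter_pool(self, pip_cal):
        f = pip_cal.f0 + 0.5 * (pip_cal.fref - pip_cal.f0)
        assert pip_transport_amount(f, pip_cal) == pytest.approx(1.0)


class TestInitialVelocity:
    def test_exact_on_a_line(self):
        t = np.linspace(0, 100, 51)
        est = initial_velocity(FluorescenceTrace(t, 0.03 * t + 1.0))
        assert est.slope == pytest.approx(0.03, rel=1e-9)
        assert est.r_squared == pytest.approx(1.0)

    def test_constant_trace_zero(self):
        t = np.linspace(0, 100, 51)
        est = initial_velocity(FluorescenceTrace(t, np.full_like(t, 2.0)),
                               r2_warn=0.0)
        assert est.slope == pytest.approx(0.0, abs=1e-12)

    def test_exponential_early_slope_matches_taylor(self):
        # y = A(1 − e^{−kt}) has initial slope A·k
        A, k = 5.0, 0.2
        t = np.linspace(0, 0.05 / k, 200)
        est = initial_velocity(FluorescenceTrace(t, A * (1 - np.exp(-k * t))))
        assert est.slope == pytest.approx(A * k, rel=0.03)

    def test_offset_invariance_and_scaling(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 50, 101)
        y = 0.1 * t + 0.01 * rng.normal(size=t.size)
        base = initial_velocity(FluorescenceTrace(t, y), r2_warn=0.0).slope
        shifted = initial_velocity(FluorescenceTrace(t, y + 7.0), r2_warn=0.0).slope
        scaled = initial_velocity(FluorescenceTrace(t, 3.0 * y), r2_warn=0.0).slope
        assert shifted == pytest.approx(base, rel=1e-9)
        assert scaled == pytest.approx(3.0 * base, rel=1e-9)

    def test_nonlinear_window_warns(self):
        t = np.linspace(0, 100, 101)
        with pytest.warns(UserWarning, match="not linear"):
            initial_velocity(FluorescenceTrace(t, 5 * (1 - np.exp(-0.5 * t))))

    def test_too_few_points_rejected(self):
        tr = FluorescenceTrace([0.0, 1.0, 2.0, 3.0], [0.0, 1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match=">= 3"):
            initial_velocity(tr, window=np.array([0, 1]))

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            FluorescenceTrace([0.0, 1.0, 1.0], [0.0, 0.1, 0.2])


class TestVelocityArithmetic:
    @pytest.mark.parametrize(
        "vp,vb,expected", [(0.5, 0.1, 0.4), (0.3, 0.0, 0.3), (0.2, 0.2, 0.0)]
    )
    def test_background_subtract(self, vp, vb, expected):
        assert background_subtract(vp, vb) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "vc,vb,expected", [(1.8, 0.1, 18.0), (0.7, 0.7, 1.0), (0.0, 0.5, 0.0)]
    )
    def test_fold_stimulation(self, vc, vb, expected):
        assert fold_stimulation(vc, vb) == pytest.approx(expected)

    def test_fold_requires_positive_basal(self):
        with pytest.raises(ValueError, match="basal"):
            fold_stimulation(1.0, 0.0)
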