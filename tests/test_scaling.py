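"""Hydrodynamic scaling map: closed forms, peak location, model variants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from actonem.motor_kinetics import MicroscopicCurves, default_atp_grid
from actonem.scaling import (
    HydroCurves, MMParams, ScalingParams, activity_from_strain,
    elastic_constant, find_speed_peak, hydrodynamic_prediction,
    mm_microscopic_curves, predict_curves,
)


def test_activity_power_law():
    assert activity_from_strain(1.0) == pytest.approx(1.0)
    assert activity_from_strain(0.7, beta=0.0) == pytest.approx(1.0)
    assert activity_from_strain(0.5, beta=0.1) == pytest.approx(0.93303,
                                                               abs=1e-5)
    assert activity_from_strain(0.0, beta=0.1) == 0.0
    with pytest.raises(ValueError):
        activity_from_strain(-0.1)


def test_elastic_constant_composition():
    assert elastic_constant(0.9, ScalingParams(kappa=0.0)) == \
        pytest.approx(0.001)
    assert elastic_constant(0.0, ScalingParams()) == pytest.approx(0.001)
    p = ScalingParams(k0=0.001, kappa=0.01, c_m=1.0, c_p=0.0)
    assert elastic_constant(0.43, p) == pytest.approx(0.0053)
    with pytest.raises(ValueError):
        elastic_constant(1.2, p)


def test_hydrodynamic_closed_forms():
    v, ell = hydrodynamic_prediction(0.004, 0.01, eta=1.0)
    assert ell == pytest.approx(0.63246, abs=1e-5)
    assert v == pytest.approx(0.0063246, abs=1e-6)
    v1, ell1 = hydrodynamic_prediction(0.01, 0.01)
    assert ell1 == pytest.approx(1.0)
    v0, ell0 = hydrodynamic_prediction(1.0, 0.0)
    assert np.isinf(ell0) and v0 == 0.0


@settings(deadline=None, derandomize=True)
@given(k=st.floats(1e-6, 1e3), a=st.floats(1e-6, 1e3), eta=st.floats(0.1, 10))
def test_hydrodynamic_identities(k, a, eta):
    """v = l * alpha / eta exactly, and l scales as sqrt(K)."""
    v, ell = hydrodynamic_prediction(k, a, eta)
    assert v == pytest.approx(ell * a / eta, rel=1e-12)
    _, ell2 = hydrodynamic_prediction(2 * k, a, eta)
    assert ell2 / ell == pytest.approx(np.sqrt(2.0), rel=1e-12)


def test_mm_curves_shapes_and_limits():
    params = MMParams()
    curves = mm_microscopic_curves(np.array([1.0, 10.0, 1e9]), params)
    vm = curves.epsilon / curves.p_cl
    assert np.all(np.diff(vm) > 0)                 # motor speed rises
    assert np.all(np.diff(curves.p_cl) < 0)       # crosslinking falls
    assert vm[-1] == pytest.approx(params.v_max, rel=1e-6)
    assert curves.p_cl[-1] == pytest.approx(params.p_floor, rel=1e-4)
    with pytest.raises(ValueError):
        MMParams(p_floor=0.5, p_max=0.4)


def test_mm_strain_peak_against_dense_oracle():
    """Coarse-grid argmax of epsilon agrees with a dense-grid brute-force
    evaluation within one coarse grid step."""
    coarse = mm_microscopic_curves(default_atp_grid(40))
    dense = mm_microscopic_curves(default_atp_grid(100_000))
    a_coarse = coarse.atp[np.argmax(coarse.epsilon)]
    a_dense = dense.atp[np.argmax(dense.epsilon)]
    step = coarse.atp[1] / coarse.atp[0]
    assert a_coarse / step <= a_dense <= a_coarse * step


def _monotone_micro(n=40):
    """Curves with monotonically rising strain rate and falling P_cl, the
    structure of the simulated motor curves."""
    atp = default_atp_grid(n)
    return MicroscopicCurves(atp=atp, epsilon=atp / (atp + 50.0),
                             p_cl=0.05 + 0.95 * 50.0 / (50.0 + atp))


def test_predict_curves_constant_elasticity_monotone():
    """kappa = 0 (constant K): with a monotone strain rate, speed rises and
    length falls with [ATP]."""
    h = predict_curves(_monotone_micro(), ScalingParams(kappa=0.0))
    assert np.all(np.diff(h.v) > 0)
    assert np.all(np.diff(h.ell) < 0)
    assert h.v.max() == pytest.approx(1.0)
    assert h.ell.max() == pytest.approx(1.0)


def test_predict_curves_crosslink_elasticity_interior_peak():
    """kappa = 10 K0, beta = 0.1: speed peaks at intermediate [ATP] while
    the nematic length still falls."""
    h = predict_curves(mm_microscopic_curves(), ScalingParams())
    pk = find_speed_peak(h)
    assert not pk.boundary_flag
    assert np.all(np.diff(h.ell) < 0)
    assert pk.k_prime_at_peak <= 0.0


def test_speed_peak_against_dense_brute_force():
    """Synthetic alpha(A) = A/(A+50), K(A) = 1 + 450/(A+50): the coarse-grid
    peak matches the dense-grid argmax of sqrt(K*alpha) within one step."""
    def curves_on(atp):
        alpha = atp / (atp + 50.0)
        k = 1.0 + 450.0 / (atp + 50.0)
        v = np.sqrt(k * alpha)
        return HydroCurves(atp=atp, alpha=alpha, k_elastic=k,
                           v=v / v.max(), ell=np.sqrt(k / alpha))
    coarse_grid = default_atp_grid(40)
    pk = find_speed_peak(curves_on(coarse_grid))
    dense = curves_on(default_atp_grid(10_000))
    a_dense = dense.atp[np.argmax(dense.v)]
    step = coarse_grid[1] / coarse_grid[0]
    assert not pk.boundary_flag
    assert pk.atp_peak / step <= a_dense <= pk.atp_peak * step


def test_stationarity_residual_vanishes_on_refined_grid():
    """At an interior peak, |K' alpha + K alpha'| (normalized) <= 1e-3 after
    grid refinement."""
    h = predict_curves(mm_microscopic_curves(default_atp_grid(10_000)))
    pk = find_speed_peak(h)
    assert not pk.boundary_flag
    assert pk.residual <= 1e-3


def test_monotone_speed_flags_boundary_peak():
    h = predict_curves(_monotone_micro(), ScalingParams(kappa=0.0))
    pk = find_speed_peak(h)
    assert pk.boundary_flag
    assert pk.atp_peak == h.atp[-1]


def test_kappa_shifts_peak_to_lower_atp():
    """On a dense grid the peak moves strictly left as kappa grows."""
    mm = mm_microscopic_curves(default_atp_grid(2000))
    peaks = [find_speed_peak(predict_curves(mm, ScalingParams(kappa=r * 0.001))
                             ).atp_peak for r in (5, 10, 20)]
    assert peaks[0] > peaks[1] > peaks[2]


def test_passive_crosslinker_shifts_peak_up_and_lengthens():
    """Adding c_p raises K everywhere: un-normalized l grows pointwise and
    the speed peak moves to higher [ATP]."""
    mm = mm_microscopic_curves(default_atp_grid(2000))
    h0 = predict_curves(mm, ScalingParams(c_p=0.0))
    h1 = predict_curves(mm, ScalingParams(c_p=0.5))
    assert find_speed_peak(h1).atp_peak >= find_speed_peak(h0).atp_peak
    assert np.all(h1.ell * h1.ell_scale > h0.ell * h0.ell_scale)


def test_refined_peak_stays_within_a_grid_step():
    mm = mm_microscopic_curves()
    pk = find_speed_peak(predict_curves(mm), refine=10)
    step = mm.atp[1] / mm.atp[0]
    assert pk.atp_peak / step <= pk.atp_peak_refined <= pk.atp_peak * step


def test_scaling_params_validation():
    with pytest.raises(ValueError):
        ScalingParams(k0=0.0)
    with pytest.raises(ValueError):
        ScalingParams(beta=3.0)
    with pytest.raises(ValueError):
        ScalingParams(c_p=-1.0)
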