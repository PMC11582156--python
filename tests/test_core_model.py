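"""Forward-model unit and property tests.

Frozen expected values were computed from the closed-form definitions
(lineshapes, derived-rate formulas) or from the brute-force RK4 oracle in
``_oracles.py``.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uteqmt.core_model import (
    LineshapeKind,
    MTProtocol,
    SaturationPulse,
    SequenceTiming,
    TissueParams,
    absorption_lineshape,
    derive_kba,
    derive_r1a,
    pulse_omega1_rms,
    saturation_rates,
    simulate_signal,
    simulate_spectrum,
)

from _oracles import mmf_kab_single_pool_limit, oracle_spectrum


def _params(**kw):
    base = dict(mmf=0.5, k_ab=25.0, t1_obs=0.24, t2a=0.8e-3)
    base.update(kw)
    return TissueParams(**base)


class TestDerivedRates:
    def test_r1a_collapses_to_r1obs_without_exchange(self):
        p = TissueParams(mmf=0.5, k_ab=0.0, t1_obs=0.25, t2a=0.8e-3)
        assert derive_r1a(p) == pytest.approx(4.0)

    def test_r1a_equals_r1obs_when_pools_relax_equally(self):
        # R1b = R1obs makes the correction term vanish for any exchange
        for k_ab, mmf in [(5.0, 0.2), (60.0, 0.55)]:
            p = TissueParams(mmf=mmf, k_ab=k_ab, t1_obs=0.5, t2a=0.8e-3, r1b=2.0)
            assert derive_r1a(p) == pytest.approx(2.0, rel=1e-12)

    def test_r1a_midpoint_value(self):
        # direct evaluation of the R1obs-inversion formula
        assert derive_r1a(_params()) == pytest.approx(7.79262086513995, rel=1e-10)

    def test_degenerate_denominator_raises(self):
        # R1b - R1obs + k_ba == 0: r1b=4.1667-25+... choose k_ba = r1obs - r1b
        r1obs = 1 / 0.25
        k_ba_target = r1obs - 1.0  # with r1b = 1
        mmf = 0.5  # k_ba = k_ab
        p = TissueParams(mmf=mmf, k_ab=k_ba_target, t1_obs=0.25, t2a=0.8e-3)
        with pytest.raises(ZeroDivisionError):
            derive_r1a(p)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        mmf=st.floats(0.30, 0.60),
        k_ab=st.floats(10.0, 60.0),
        t1_obs=st.floats(0.22, 0.28),
    )
    def test_slow_eigenvalue_recovers_r1obs(self, mmf, k_ab, t1_obs):
        """The R1a relation inverts the slow eigenvalue of the two-pool
        longitudinal relaxation-exchange matrix (bone regime, where the
        bound-pool mode k_ba + R1b is always the fast one)."""
        p = TissueParams(mmf=mmf, k_ab=k_ab, t1_obs=t1_obs, t2a=0.8e-3)
        r1a, k_ba = derive_r1a(p), derive_kba(p)
        A = np.array([[-(r1a + p.k_ab), k_ba], [p.k_ab, -(p.r1b + k_ba)]])
        slow = -np.max(np.linalg.eigvals(A).real)
        assert slow == pytest.approx(1.0 / t1_obs, rel=1e-6)

    @pytest.mark.parametrize(
        "mmf,k_ab,expected",
        [(0.5, 25.0, 25.0), (0.3, 10.0, 23.333333333333332), (0.999, 40.0, 0.04004004004004004)],
    )
    def test_kba_values(self, mmf, k_ab, expected):
        p = TissueParams(mmf=mmf, k_ab=k_ab, t1_obs=0.24, t2a=0.8e-3)
        assert derive_kba(p) == pytest.approx(expected, rel=1e-6)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(mmf=st.floats(0.01, 0.99), k_ab=st.floats(0.0, 500.0))
    def test_kba_detailed_balance_and_involution(self, mmf, k_ab):
        p = TissueParams(mmf=mmf, k_ab=k_ab, t1_obs=0.24, t2a=0.8e-3)
        k_ba = derive_kba(p)
        assert k_ba * mmf == pytest.approx(k_ab * (1 - mmf), abs=1e-12 * max(1, k_ab))
        # swapping pool labels (mmf -> 1-mmf, k_ab <-> k_ba) is an involution
        q = TissueParams(mmf=1 - mmf, k_ab=k_ba, t1_obs=0.24, t2a=0.8e-3)
        assert derive_kba(q) == pytest.approx(k_ab, rel=1e-12, abs=1e-12)

    def test_invalid_mmf_rejected(self):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                TissueParams(mmf=bad, k_ab=10.0, t1_obs=0.24, t2a=0.8e-3)


class TestLineshapes:
    def test_on_resonance_values(self):
        assert absorption_lineshape(0.0, 15e-6, "gaussian") == pytest.approx(
            15e-6 / np.sqrt(2 * np.pi), rel=1e-12
        )
        assert absorption_lineshape(0.0, 0.8e-3, "lorentzian") == pytest.approx(
            0.8e-3 / np.pi, rel=1e-12
        )

    @pytest.mark.parametrize("kind", ["gaussian", "lorentzian"])
    def test_nonnegative_and_decreasing(self, kind):
        offsets = np.array([0.0, 1e3, 2e3, 5e3, 1e4, 5e4, 1e6])
        t2 = 15e-6 if kind == "gaussian" else 0.8e-3
        g = absorption_lineshape(offsets, t2, kind)
        assert np.all(g >= 0)
        assert np.all(np.diff(g) < 0)
        assert g[-1] < 1e-3 * g[0]  # vanishes far off resonance

    def test_super_lorentzian_cutoff_guard(self):
        with pytest.raises(ValueError):
            absorption_lineshape(500.0, 15e-6, "super_lorentzian")
        v_cut = absorption_lineshape(
            500.0, 15e-6, "super_lorentzian", sl_extrapolate=True
        )
        assert v_cut == pytest.approx(
            absorption_lineshape(1e3, 15e-6, "super_lorentzian"), rel=1e-12
        )
        # far off resonance all lineshapes decay
        assert absorption_lineshape(5e4, 15e-6, "super_lorentzian") < v_cut


class TestSaturationRates:
    def test_zero_power_gives_zero_rates(self):
        p = _params()
        pulse = SaturationPulse(0.0, 10e3)
        assert saturation_rates(pulse, p) == (0.0, 0.0)

    @pytest.mark.parametrize("shape", ["rect", "fermi", "gaussian"])
    def test_quadratic_power_scaling(self, shape):
        p = _params()
        w1, _ = saturation_rates(SaturationPulse(400.0, 10e3, shape=shape), p)
        w2, _ = saturation_rates(SaturationPulse(800.0, 10e3, shape=shape), p)
        assert w2 == pytest.approx(4.0 * w1, rel=1e-10)

    def test_offset_dependence_follows_lineshape(self):
        # for a rect pulse W_b(2k)/W_b(50k) is exactly G(2k)/G(50k)
        p = _params()
        w_2k, _ = saturation_rates(SaturationPulse(400.0, 2e3, 8e-3, "rect"), p)
        w_50k, _ = saturation_rates(SaturationPulse(400.0, 50e3, 8e-3, "rect"), p)
        ratio = absorption_lineshape(2e3, p.t2b) / absorption_lineshape(50e3, p.t2b)
        assert w_2k / w_50k == pytest.approx(ratio, rel=1e-10)
        assert w_2k > w_50k

    def test_rect_rms_equals_mean_amplitude(self):
        theta = np.deg2rad(400.0)
        assert pulse_omega1_rms(400.0, 8e-3, "rect") == pytest.approx(
            theta / 8e-3, rel=1e-9
        )
        # shaped pulses need higher RMS power for the same flip angle
        assert pulse_omega1_rms(400.0, 8e-3, "fermi") > theta / 8e-3
        assert pulse_omega1_rms(400.0, 8e-3, "gaussian") > theta / 8e-3


class TestSimulateSignal:
    def test_zero_power_baseline_is_offset_independent(self, midpoint):
        vals = [
            simulate_signal(midpoint, SaturationPulse(0.0, off))
            for off in (2e3, 10e3, 50e3)
        ]
        assert np.ptp(vals) < 1e-12 * vals[0]
        assert vals[0] > 0

    def test_decoupled_limit_matches_single_pool_steady_state(self, protocol):
        p = TissueParams(mmf=1e-4, k_ab=1e-9, t1_obs=0.24, t2a=0.8e-3)
        full = simulate_spectrum(p, protocol)
        limit = mmf_kab_single_pool_limit(p, protocol)
        assert full == pytest.approx(limit, rel=1e-6)

    def test_matches_fine_step_ode_integration(self, midpoint, protocol):
        """Matrix-exponential steady state vs RK4 time-domain integration of
        the same piecewise-constant two-pool ODE (dt = 5 us)."""
        ours = simulate_spectrum(midpoint, protocol)
        brute = oracle_spectrum(midpoint, protocol)
        assert np.max(np.abs(ours / brute - 1)) < 5e-3

    def test_first_spoke_reads_below_spoke_average(self, midpoint):
        # Mz recovers from the saturation pulse along the spoke train (the
        # small-angle excitations remove less than relaxation restores), so
        # the first spoke reads lowest
        pulse = SaturationPulse(1200.0, 2e3)
        s_first = simulate_signal(midpoint, pulse, spoke_average=False)
        s_mean = simulate_signal(midpoint, pulse, spoke_average=True)
        assert 0 < s_first < s_mean

    def test_spectrum_grid_consistency(self, midpoint, protocol):
        spec = simulate_spectrum(midpoint, protocol)
        assert spec.shape == (3, 5)
        one = MTProtocol(powers_deg=(800.0,), offsets_hz=(5e3,))
        assert simulate_spectrum(midpoint, one)[0, 0] == pytest.approx(
            spec[1, 1], rel=1e-12
        )

    def test_monotone_in_power_and_offset_across_grid(self):
        from uteqmt.phantom import default_parameter_grid

        proto = MTProtocol()
        for chip in default_parameter_grid():
            s = simulate_spectrum(chip, proto)
            assert np.all(np.diff(s, axis=0) <= 1e-10), chip
            assert np.all(np.diff(s, axis=1) >= -1e-10), chip

    def test_numba_and_numpy_paths_agree(self, midpoint, protocol):
        import uteqmt.core_model as cm

        if not cm._HAVE_NUMBA:
            pytest.skip("numba not available; only one path exists")
        model = cm.SpectrumModel(protocol)
        args = (100.0, 0.5, 25.0, 1 / 0.24, 0.8e-3)
        fast = model.spectrum(*args)
        cm._HAVE_NUMBA = False
        try:
            slow = model.spectrum(*args)
        finally:
            cm._HAVE_NUMBA = True
        assert fast == pytest.approx(slow, rel=1e-12)

    def test_timing_invariant_enforced(self):
        timing = SequenceTiming(tr_s=0.05, n_spokes=13, inter_spoke_tr_s=5e-3)
        with pytest.raises(ValueError):
            timing.recovery_s(8e-3)
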