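"""Limiting-flux law and the batch ultrafiltration ODE simulator."""

import numpy as np
import pytest

from fructanuf import (
    FluxModelParams,
    SolutePair,
    UFSystemSpec,
    concentration_profiles,
    limiting_flux,
    rhs,
    simulate,
)
from conftest import rk4_trajectory


class TestLimitingFlux:
    def test_zero_exactly_at_limit_concentration(self, flux_params):
        for ro in (0.5, 0.795, 1.0):
            assert limiting_flux(flux_params.c_lim, ro, flux_params) == 0.0

    def test_ro_one_reduces_to_log_law(self, flux_params):
        # at C = C_lim / e the flux equals k
        c = flux_params.c_lim / np.e
        assert limiting_flux(c, 1.0, flux_params) == pytest.approx(
            flux_params.k, rel=1e-12)

    def test_hand_computed_value(self, flux_params):
        # ln(337.61/(0.8*100) - 0.25) = 1.3789 -> J = 8.701e-6 m/s
        assert limiting_flux(100.0, 0.8, flux_params) == pytest.approx(
            8.701e-6, abs=2e-9)

    def test_strictly_decreasing_in_concentration(self, flux_params):
        cs = np.linspace(10, flux_params.c_lim, 200)
        js = [limiting_flux(c, 0.795, flux_params) for c in cs]
        assert all(a > b or (a == b == 0) for a, b in zip(js, js[1:]))
        assert js[-1] == 0.0

    def test_clamped_to_zero_beyond_limit(self, flux_params):
        assert limiting_flux(2 * flux_params.c_lim, 0.8, flux_params) == 0.0

    def test_invalid_inputs(self, flux_params):
        with pytest.raises(ValueError):
            limiting_flux(-5.0, 0.8, flux_params)
        with pytest.raises(ValueError):
            limiting_flux(100.0, 0.0, flux_params)
        with pytest.raises(ValueError):
            FluxModelParams(k=-1e-6, c_lim=300.0)


class TestRhs:
    def test_hand_computed_derivatives(self, batch_spec):
        d = rhs([0.1, 100.0, 20.0], batch_spec)
        j = limiting_flux(100.0, batch_spec.ro.fc, batch_spec.flux_params)
        assert d[0] == pytest.approx(-j * batch_spec.area, rel=1e-12)
        assert d[1] == pytest.approx(100.0 / 0.1 * j * batch_spec.area * 0.795,
                                     rel=1e-12)

    def test_all_zero_when_flux_zero(self, flux_params):
        spec = UFSystemSpec(area=0.5, v0=0.1,
                            c0=SolutePair(fc=flux_params.c_lim + 10, fos=20.0),
                            ro=SolutePair(fc=0.8, fos=0.5), flux_params=flux_params)
        np.testing.assert_array_equal(rhs([0.1, flux_params.c_lim + 10, 20.0], spec),
                                      [0.0, 0.0, 0.0])

    def test_free_passage_solute_stays_constant(self, flux_params):
        spec = UFSystemSpec(area=0.5, v0=0.1, c0=SolutePair(fc=100.0, fos=20.0),
                            ro=SolutePair(fc=0.8, fos=0.0), flux_params=flux_params)
        d = rhs([0.1, 100.0, 20.0], spec)
        assert d[2] == 0.0
        assert d[0] < 0

    def test_nonpositive_volume_rejected(self, batch_spec):
        with pytest.raises(ValueError):
            rhs([0.0, 100.0, 20.0], batch_spec)


class TestSimulate:
    def test_volume_and_solute_conservation(self, batch_spec):
        traj = simulate(batch_spec, t_end=2 * 3600.0)
        v0 = batch_spec.v0
        np.testing.assert_allclose(traj.volume + traj.v_perm, v0, rtol=1e-9)
        for s in ("fc", "fos"):
            m0 = getattr(batch_spec.c0, s) * v0
            audit = traj.c_ret[s] * traj.volume + traj.m_perm[s]
            np.testing.assert_allclose(audit, m0, rtol=1e-6)

    def test_permeate_is_pointwise_rejection_complement(self, batch_spec):
        traj = simulate(batch_spec, t_end=3600.0)
        for s in ("fc", "fos"):
            ro = getattr(batch_spec.ro, s)
            np.testing.assert_allclose(traj.c_perm[s], traj.c_ret[s] * (1 - ro),
                                       rtol=1e-12)

    def test_full_retention_conserves_retained_mass(self, flux_params):
        spec = UFSystemSpec(area=0.5, v0=0.1, c0=SolutePair(fc=71.6, fos=17.1),
                            ro=SolutePair(fc=1.0, fos=1.0), flux_params=flux_params)
        traj = simulate(spec, t_end=4 * 3600.0, rtol=1e-10, atol=1e-12)
        for s in ("fc", "fos"):
            m0 = getattr(spec.c0, s) * spec.v0
            np.testing.assert_allclose(traj.c_ret[s] * traj.volume, m0, rtol=1e-8)

    def test_analytic_power_law_invariant(self, batch_spec):
        """dC/C = -Ro dV/V integrates to C = C0 (V0/V)^Ro exactly."""
        traj = simulate(batch_spec, t_end=3600.0)
        for s in ("fc", "fos"):
            ro = getattr(batch_spec.ro, s)
            expected = getattr(batch_spec.c0, s) * (batch_spec.v0 / traj.volume) ** ro
            np.testing.assert_allclose(traj.c_ret[s], expected, rtol=1e-7)

    def test_saturated_feed_terminates_immediately(self, flux_params):
        spec = UFSystemSpec(area=0.5, v0=0.1,
                            c0=SolutePair(fc=flux_params.c_lim + 1.0, fos=10.0),
                            ro=SolutePair(fc=0.8, fos=0.5), flux_params=flux_params)
        traj = simulate(spec, t_end=3600.0)
        assert traj.termination == "flux_zero"
        assert traj.t.size == 1

    def test_volume_event_stops_run(self, batch_spec):
        traj = simulate(batch_spec, t_end=100 * 3600.0, v_min_frac=0.5)
        assert traj.termination == "v_min"
        assert traj.volume[-1] == pytest.approx(0.5 * batch_spec.v0, rel=1e-6)

    def test_volume_strictly_nonincreasing(self, batch_spec):
        traj = simulate(batch_spec, t_end=3600.0)
        assert np.all(np.diff(traj.volume) <= 0)

    def test_adaptive_matches_fixed_step_rk4_oracle(self, batch_spec):
        """One-hour reference run: adaptive solver vs RK4 at dt = 0.1 s."""
        ts, ys = rk4_trajectory(batch_spec, 3600.0, 0.1)
        traj = simulate(batch_spec, t_end=3600.0)
        sample = ts[::3600]  # every 360 s
        prof = concentration_profiles(traj, sample)
        np.testing.assert_allclose(prof["c_fc_ret"], ys[::3600, 1], rtol=1e-5)
        np.testing.assert_allclose(prof["c_fos_ret"], ys[::3600, 2], rtol=1e-5)
        v = np.interp(sample, traj.t, traj.volume)
        np.testing.assert_allclose(v, ys[::3600, 0], rtol=1e-5)

    def test_invalid_run_parameters(self, batch_spec):
        with pytest.raises(ValueError):
            simulate(batch_spec, t_end=0.0)
        with pytest.raises(ValueError):
            simulate(batch_spec, t_end=10.0, v_min_frac=1.5)


class TestConcentrationProfiles:
    def test_grid_points_reproduced_exactly(self, batch_spec):
        traj = simulate(batch_spec, t_end=3600.0)
        prof = concentration_profiles(traj, traj.t[::50])
        np.testing.assert_allclose(prof["c_fc_ret"], traj.c_ret["fc"][::50],
                                   rtol=1e-12)
        np.testing.assert_allclose(prof["c_fos_perm"], traj.c_perm["fos"][::50],
                                   rtol=1e-12)

    def test_retentate_series_nondecreasing_under_rejection(self, batch_spec):
        traj = simulate(batch_spec, t_end=3600.0)
        prof = concentration_profiles(traj, np.linspace(0, 3600, 50))
        assert np.all(np.diff(prof["c_fc_ret"]) >= -1e-12)

    def test_permeate_retentate_ratio_constant(self, batch_spec):
        traj = simulate(batch_spec, t_end=3600.0)
        prof = concentration_profiles(traj, np.linspace(0, 3600, 20))
        ratio = prof["c_fc_perm"] / prof["c_fc_ret"]
        np.testing.assert_allclose(ratio, 1 - batch_spec.ro.fc, rtol=1e-9)

    def test_out_of_span_times_rejected(self, batch_spec):
        traj = simulate(batch_spec, t_end=100.0)
        with pytest.raises(ValueError, match="span"):
            concentration_profiles(traj, [200.0])
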