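"""Waveform processing, shear indices and Windkessel network tests."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nihsim import (
    FlowWaveform,
    WindkesselElement,
    WindkesselNetwork,
    compute_field,
    flow_rate_from_vmax,
    make_graft,
    osi,
    parabolic_profile,
    rrt,
    smooth_waveform,
    solve_windkessel,
    station_wss,
    steady_flow_split,
    tawss,
)
from nihsim.hemodynamics import ShearSeries, calibrate_outlet_parameters
from nihsim.synthetic_data import disturbance_profile, fixture_network


def make_wave(v, period=1.1, kind="flow"):
    v = np.asarray(v, dtype=float)
    t = np.arange(v.size) * period / v.size
    return FlowWaveform(t=t, v=v, period=period, kind=kind)


class TestWaveform:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            make_wave(np.ones(4))  # too few samples
        with pytest.raises(ValueError):
            FlowWaveform(t=np.linspace(0, 1.2, 16), v=np.ones(16), period=1.1)

    def test_periodic_sampling(self):
        w = make_wave(np.sin(2 * np.pi * np.arange(64) / 64))
        np.testing.assert_allclose(w.sample(w.t + 3 * w.period), w.v, atol=1e-12)


class TestSmoothing:
    def test_constant_unchanged_and_identity_window(self):
        w = make_wave(np.full(32, 3.7))
        np.testing.assert_allclose(smooth_waveform(w, 5).v, 3.7)
        spiky = make_wave(np.arange(32.0))
        np.testing.assert_allclose(smooth_waveform(spiky, 1).v, spiky.v)

    def test_spike_spread_conserves_sum(self):
        v = np.zeros(16)
        v[8] = 1.0
        sm = smooth_waveform(make_wave(v), 3)
        np.testing.assert_allclose(sm.v[7:10], 1 / 3)
        assert sm.v.sum() == pytest.approx(1.0)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_waveform(make_wave(np.ones(16)), 4)

    @given(st.lists(st.floats(-10, 10), min_size=9, max_size=40),
           st.integers(0, 10))
    def test_mean_preserved_max_not_increased(self, vals, half):
        w = make_wave(np.array(vals))
        window = min(2 * half + 1, len(vals) - (1 - len(vals) % 2))
        sm = smooth_waveform(w, window)
        assert np.mean(sm.v) == pytest.approx(np.mean(w.v), abs=1e-12)
        assert sm.v.max() <= w.v.max() + 1e-12


class TestProfileAndShear:
    def test_parabolic_profile(self):
        assert parabolic_profile(0.5, 0.0, 1e-3) == 0.5
        assert parabolic_profile(0.5, 1e-3, 1e-3) == 0.0
        assert parabolic_profile(0.5, 0.5e-3, 1e-3) == pytest.approx(0.375)
        with pytest.raises(ValueError):
            parabolic_profile(0.5, 2e-3, 1e-3)

    def test_flow_rate_quadrature_oracle(self):
        # Q from the analytic formula vs numeric quadrature over the disc
        vmax, R = 0.4302, 2.72e-3
        r = np.linspace(0, R, 20001)
        q_num = np.trapezoid([parabolic_profile(vmax, x, R) * 2 * np.pi * x for x in r], r)
        assert flow_rate_from_vmax(vmax, R) == pytest.approx(q_num, rel=1e-6)
        assert flow_rate_from_vmax(vmax, R) == pytest.approx(5.0e-6, rel=1e-2)
        assert flow_rate_from_vmax(0.0, R) == 0.0
        # doubling the radius quadruples the flow
        assert flow_rate_from_vmax(1.0, 2 * R) == pytest.approx(
            4 * flow_rate_from_vmax(1.0, R))

    def test_station_wss_against_velocity_gradient(self):
        # tau = mu * |du/dr| at the wall for the parabolic profile
        mu, Q, R = 0.0035, 5e-6, 2.72e-3
        vmax = 2 * Q / (np.pi * R * R)
        h = 1e-9
        dudr = (parabolic_profile(vmax, R - h, R) - parabolic_profile(vmax, R, R)) / h
        assert station_wss(Q, R, mu) == pytest.approx(mu * dudr, rel=1e-5)
        assert station_wss(Q, R, mu) == pytest.approx(1.107, abs=5e-3)
        assert station_wss(0.0, R, mu) == 0.0
        assert station_wss(Q, R / 2, mu) == pytest.approx(8 * station_wss(Q, R, mu))

    def test_occluded_station_rejected(self):
        with pytest.raises(ValueError):
            station_wss(1e-6, 0.0)


def series(tau, period=1.0):
    tau = np.asarray(tau, dtype=float)
    t = np.arange(tau.size) * period / tau.size
    return ShearSeries(station_id="s", t=t, tau=tau, period=period)


class TestIndices:
    def test_tawss(self):
        assert tawss(series(np.full(64, 0.3))) == pytest.approx(0.3)
        square = np.where(np.arange(64) < 32, 1.0, -1.0)
        assert tawss(series(square)) == pytest.approx(1.0)
        t = np.linspace(0, 1, 2000, endpoint=False)
        assert tawss(series(np.sin(2 * np.pi * t))) == pytest.approx(2 / np.pi, rel=1e-4)

    def test_osi(self):
        assert osi(series(np.full(64, 0.4))) == 0.0
        t = np.linspace(0, 1, 2000, endpoint=False)
        assert osi(series(np.sin(2 * np.pi * t))) == pytest.approx(0.5, abs=1e-6)
        three_quarters = np.where(np.arange(4000) < 3000, 1.0, -1.0)
        assert osi(series(three_quarters)) == pytest.approx(0.25, rel=1e-2)

    def test_rrt(self):
        assert rrt(1.0, 0.0) == 1.0
        assert rrt(1.0, 0.25) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            rrt(1.0, 0.5)

    @given(st.lists(st.floats(-5, 5), min_size=8, max_size=64))
    def test_index_identities(self, taus):
        s = series(np.array(taus))
        ta, o = tawss(s), osi(s)
        assert 0.0 <= o <= 0.5
        t, tau = s.t, s.tau
        mean_signed = abs(np.trapezoid(np.append(tau, tau[0]),
                                       np.append(t, 1.0))) / 1.0
        assert ta >= mean_signed - 1e-12
        if ta > 1e-12 and o < 0.5:
            assert rrt(ta, o) * (1 - 2 * o) * ta == pytest.approx(1.0)


class TestWindkessel:
    def test_flow_split_conductance_ratio(self):
        np.testing.assert_allclose(steady_flow_split([3e3, 2e3]), [0.4, 0.6])
        np.testing.assert_allclose(steady_flow_split([7.0] * 4), 0.25)
        bank = [5.5e5, 4.5e5, 4.5e5, 3e3, 2e3]
        g = 1 / np.asarray(bank)
        np.testing.assert_allclose(steady_flow_split(bank), g / g.sum())
        with pytest.raises(ValueError):
            steady_flow_split([])

    def test_pure_resistance_is_ohmic(self):
        net = WindkesselNetwork({"a": WindkesselElement(R=2e8, C=0.0)})
        q0 = 5e-6
        sol = solve_windkessel(net, make_wave(np.full(64, q0)), n_cycles=2)
        np.testing.assert_allclose(sol.pressure, q0 * 2e8, rtol=1e-12)

    def test_rc_step_matches_analytic_exponential(self):
        R, C = 2e8, 1e-8  # time constant RC = 2 s
        net = WindkesselNetwork({"a": WindkesselElement(R=R, C=C)})
        q0 = 5e-6
        wave = make_wave(np.full(200, q0), period=1.0)
        sol = solve_windkessel(net, wave, dt=1.0 / 1000, n_cycles=12)
        # reconstruct absolute time of the returned (last) cycle from convergence:
        # run long enough that P ~ Q0*R*(1-exp(-t/RC)); compare shapes via the ODE
        # solution starting from the cycle's initial pressure
        p0 = sol.pressure[0]
        expected = q0 * R + (p0 - q0 * R) * np.exp(-sol.t / (R * C))
        np.testing.assert_allclose(sol.pressure, expected, rtol=1e-3)

    def test_resistive_split_matches_steady_split_instantaneously(self):
        net = WindkesselNetwork({"a": WindkesselElement(R=3e9),
                                 "b": WindkesselElement(R=2e9)})
        t = np.arange(64) / 64 * 1.1
        wave = make_wave(1e-6 * (1 + 0.5 * np.sin(2 * np.pi * t / 1.1)))
        sol = solve_windkessel(net, wave, n_cycles=2)
        total = sol.outlet_flows["a"] + sol.outlet_flows["b"]
        np.testing.assert_allclose(sol.outlet_flows["a"], 0.4 * total, rtol=1e-10)
        # mass conservation at every instant for the resistive bank
        np.testing.assert_allclose(total, wave.sample(sol.t), rtol=1e-9)

    def test_compliant_bank_conserves_cycle_mean(self):
        net = WindkesselNetwork({
            "a": WindkesselElement(R=3e9, C=1.26e-11),
            "b": WindkesselElement(R=2e9, C=1.26e-11)})
        t = np.arange(128) / 128 * 1.1
        wave = make_wave(1e-6 * (1 + 0.5 * np.sin(2 * np.pi * t / 1.1)))
        sol = solve_windkessel(net, wave, n_cycles=20)
        out_mean = sum(np.trapezoid(q, sol.t) for q in sol.outlet_flows.values()) / 1.1
        assert out_mean == pytest.approx(wave.mean, rel=0.01)

    def test_calibration_recovers_target_split(self):
        net = WindkesselNetwork({"a": WindkesselElement(R=1e9),
                                 "b": WindkesselElement(R=1e9)})
        wave = make_wave(np.full(64, 1e-6), period=1.1)
        targets = {"a": 0.4e-6, "b": 0.6e-6}
        cal = calibrate_outlet_parameters(net, targets, wave)
        assert cal.elements["a"].R / cal.elements["b"].R == pytest.approx(1.5, rel=0.05)
        sol = solve_windkessel(cal, wave, n_cycles=4)
        for k, target in targets.items():
            mean = np.trapezoid(sol.outlet_flows[k], sol.t) / 1.1
            assert mean == pytest.approx(target, rel=0.011)

    def test_infeasible_targets_rejected(self):
        net = WindkesselNetwork({"a": WindkesselElement(R=1e9)})
        wave = make_wave(np.full(64, 1e-6))
        with pytest.raises(ValueError):
            calibrate_outlet_parameters(net, {"a": 2e-6}, wave)


class TestComputeField:
    def test_straight_tube_poiseuille_uniform(self):
        from nihsim import FixtureSpec
        tree = make_graft("straight_tube", FixtureSpec(preset="straight_tube"))
        wave = make_wave(np.full(64, 5e-6), period=1.1)
        fields = compute_field(tree, wave, fixture_network("straight_tube"))
        vals = [f.tawss for f in fields]
        np.testing.assert_allclose(vals, vals[0], rtol=1e-12)
        assert vals[0] == pytest.approx(station_wss(5e-6, 2.7e-3), rel=1e-9)

    def test_wider_station_sees_less_shear(self):
        from nihsim import FixtureSpec
        tree = make_graft("straight_tube", FixtureSpec(preset="straight_tube"))
        list(tree.stations())[10].radius *= 1.5
        wave = make_wave(np.full(64, 5e-6), period=1.1)
        fields = compute_field(tree, wave, fixture_network("straight_tube"))
        assert fields[10].tawss == pytest.approx(fields[0].tawss / 1.5 ** 3)

    def test_disturbance_localizes_minimum_at_distal_anastomosis(
            self, graft_tree, smooth_wave, graft_network):
        dist = disturbance_profile(graft_tree)
        fields = compute_field(graft_tree, smooth_wave, graft_network,
                               disturbance=dist)
        fmin = min(fields, key=lambda f: f.tawss)
        assert "distal_anastomosis" in fmin.tags

    def test_bifurcation_mass_conservation(self):
        tree = make_graft("femorodistal")
        net = fixture_network("femorodistal")
        wave = make_wave(np.full(64, 2e-5), period=1.1)
        fracs = dict(zip(tree.outlet_ids,
                         steady_flow_split([net.elements[k].R for k in tree.outlet_ids])))
        seg = tree.segment_flow_fractions(fracs)
        for parent, kids in tree.connectivity.items():
            assert seg[parent] == pytest.approx(sum(seg[k] for k in kids), rel=1e-12)
        assert seg[tree.inlet] == pytest.approx(1.0)
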