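"""Delayed adaptation dynamics: closures, fixed points, simulations."""

import math

import numpy as np
import pytest

import veinfate as vf
from conftest import make_random_net
from veinfate.adaptation import dangling_shear, midvein_shear
from veinfate.hydraulics import time_averaged_shear
from veinfate.network import MPAS, UM
from veinfate.timeseries import loop_orientation


def params(t_adapt=200.0, tau0=1.0, t_delay=10.0, a_min=0.05):
    return vf.AdaptationParams(t_adapt_s=t_adapt, tau0=tau0,
                               t_delay_s=t_delay, a_min_um=a_min)


class TestRightHandSides:
    def test_murray_steady_state(self):
        assert vf.adaptation_rhs(10.0, 1.0, params(tau0=1.0)) == 0.0

    def test_zero_shear_pure_shrinkage(self):
        p = params(t_adapt=100.0)
        assert vf.adaptation_rhs(8.0, 0.0, p) == pytest.approx(-8.0 / 100.0)

    def test_sqrt2_growth(self):
        p = params(t_adapt=100.0, tau0=2.0)
        assert vf.adaptation_rhs(8.0, math.sqrt(2) * 2.0, p) == \
            pytest.approx(8.0 / 100.0)

    def test_sensing_equilibrium(self):
        assert vf.sensing_rhs(1.3, 1.3, 60.0) == 0.0

    def test_sensing_step_relaxation_time_constant(self):
        # step input: exponential relaxation with time constant t_delay
        td = 60.0
        t = np.linspace(0, 600, 2001)
        from scipy.integrate import solve_ivp

        sol = solve_ivp(lambda t, y: [vf.sensing_rhs(y[0], 2.0, td)],
                        (0, 600), [0.0], t_eval=t, rtol=1e-10, atol=1e-12)
        ts = sol.y[0]
        # fit the decay of (2 - ts): slope of log should be -1/td
        resid = 2.0 - ts[200:1200]
        slope = np.polyfit(t[200:1200], np.log(resid), 1)[0]
        assert -1.0 / slope == pytest.approx(td, rel=0.01)
        assert ts[-1] == pytest.approx(2.0, rel=1e-4)


class TestShearClosures:
    def test_dangling_prefactor_is_32(self):
        L, eps, T, a = 1000e-6, 0.05, 100.0, 20e-6
        tau = dangling_shear(a, L, eps, T)
        assert tau * a * T / (L * eps) == pytest.approx(32.0, rel=1e-12)

    def test_dangling_inverse_in_radius(self):
        assert dangling_shear(10e-6, 1e-3, 0.05, 100.0) == pytest.approx(
            2 * dangling_shear(20e-6, 1e-3, 0.05, 100.0))

    def test_midvein_short_circuit_limit_is_dangling(self):
        L, eps, T = 1000e-6, 0.05, 100.0
        for a in (6e-6, 20e-6, 60e-6):
            rs = vf.ReducedSystem(length=L, eps=eps, period=T,
                                  coupling=1e-12 * a**4)
            assert midvein_shear(a, rs) == pytest.approx(
                dangling_shear(a, L, eps, T), rel=1e-6)

    def test_midvein_vanishes_at_zero_radius(self):
        rs = vf.ReducedSystem(length=1e-3, eps=0.05, period=100.0,
                              coupling=1e-20)
        assert midvein_shear(1e-12, rs) < 1e-15

    def test_midvein_equals_composed_hydraulics(self):
        # Eq-level closure == contraction_inflow ∘ poiseuille ∘ norton ∘ shear
        mu_mPas = 1.5
        rng = np.random.default_rng(1)
        for _ in range(10):
            L_um = float(rng.uniform(200, 2000))
            a_um = float(rng.uniform(5, 70))
            eps = float(rng.uniform(0.01, 0.1))
            T = float(rng.uniform(60, 120))
            R_net = float(rng.uniform(1e11, 1e15))
            c = 8 * (mu_mPas * MPAS) * (L_um * UM) / (math.pi * R_net)
            rs = vf.ReducedSystem(length=L_um * UM, eps=eps, period=T,
                                  coupling=c)
            R = vf.poiseuille_resistance(L_um, a_um, mu_mPas)
            Q = vf.norton_flow(R, R_net,
                               vf.contraction_inflow(L_um, a_um, eps, T))
            composed = vf.shear_from_flow(Q, a_um * UM)
            assert midvein_shear(a_um * UM, rs) == pytest.approx(
                composed, rel=1e-10)


class TestTargetShearFromPressure:
    def test_balanced_pressure(self):
        tau0, clipped = vf.target_shear_from_pressure(2.0, 50.0, 50.0, 1.5)
        assert tau0 == 2.0 and not clipped

    def test_reference_value(self):
        # (P - P0)/mu = 0.5 1/s at mu = 2 mPa·s -> P - P0 = 1e-3 Pa
        tau0, _ = vf.target_shear_from_pressure(2.0, 1e-3, 0.0, 2.0)
        assert tau0 == pytest.approx(1.5)

    def test_monotone_decreasing_in_pressure(self):
        vals = [vf.target_shear_from_pressure(2.0, p, 0.0, 1.5)[0]
                for p in np.linspace(0, 2e-3, 7)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_clipped_at_zero(self):
        tau0, clipped = vf.target_shear_from_pressure(1.0, 1.0, 0.0, 1.0)
        assert tau0 == 0.0 and clipped


class TestReducedFixedPoints:
    def test_reference_quartic_roots(self, nondim_reduced):
        # beta = 2.5, c = 1: positive roots 0.845 (saddle) and 2.430 (stable)
        fps = vf.reduced_fixed_points(nondim_reduced, params())
        assert len(fps) == 3
        assert fps[0].radius == 0.0 and fps[0].stability == "stable"
        assert fps[1].radius == pytest.approx(0.8455, abs=2e-4)
        assert fps[1].stability == "unstable"
        assert fps[2].radius == pytest.approx(2.4303, abs=2e-4)
        assert fps[2].stability == "stable"

    def test_beyond_saddle_node_only_origin(self):
        beta = 2.5
        c = 27 * beta**4 / 256 * 1.01
        rs = vf.ReducedSystem(length=1.0, eps=1.0, period=32.0 / beta,
                              coupling=c)
        fps = vf.reduced_fixed_points(rs, params())
        assert len(fps) == 1
        assert fps[0].stability == "stable"

    def test_two_root_count_pattern_two_stable_one_unstable(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            beta = float(rng.uniform(0.5, 4.0))
            c = float(rng.uniform(0.1, 0.95)) * 27 * beta**4 / 256
            rs = vf.ReducedSystem(length=1.0, eps=1.0, period=32.0 / beta,
                                  coupling=c)
            fps = vf.reduced_fixed_points(rs, params())
            labels = [f.stability for f in fps]
            assert labels.count("stable") == 2
            assert labels.count("unstable") == 1

    def test_stability_matches_numerical_jacobian(self, nondim_reduced):
        # finite-difference Jacobian eigenvalues agree with the analytic ones
        p = params()
        for fp in vf.reduced_fixed_points(nondim_reduced, p)[1:]:
            a0, ts0 = fp.radius, fp.tau_s

            def F(a, ts):
                return np.array([
                    vf.adaptation_rhs(a, ts, p),
                    vf.sensing_rhs(ts, midvein_shear(a, nondim_reduced),
                                   p.t_delay_s)])

            h = 1e-7
            J = np.column_stack([
                (F(a0 + h, ts0) - F(a0 - h, ts0)) / (2 * h),
                (F(a0, ts0 + h) - F(a0, ts0 - h)) / (2 * h)])
            ev = np.linalg.eigvals(J)
            got = sorted(np.real(fp.eigenvalues))
            want = sorted(ev.real)
            np.testing.assert_allclose(got, want, rtol=1e-4, atol=1e-9)

    def test_saddle_node_boundary_at_27_beta4_over_256(self):
        # bisection on c locates the two-root boundary within 1 %
        p = params()
        for beta in (1.0, 2.0, 3.0):
            c_crit = 27 * beta**4 / 256
            lo, hi = 1e-3 * c_crit, 2 * c_crit

            def n_pos(c):
                rs = vf.ReducedSystem(length=1.0, eps=1.0,
                                      period=32.0 / beta, coupling=c)
                return sum(1 for f in vf.reduced_fixed_points(rs, p)
                           if f.radius > 0)

            for _ in range(40):
                mid = 0.5 * (lo + hi)
                if n_pos(mid) == 2:
                    lo = mid
                else:
                    hi = mid
            assert 0.5 * (lo + hi) == pytest.approx(c_crit, rel=0.01)


class TestSimulateVein:
    def test_stationary_at_stable_fixed_point(self, nondim_reduced):
        p = params(t_adapt=50.0, t_delay=5.0)
        a_s = vf.reduced_fixed_points(nondim_reduced, p)[2].radius
        tr = vf.simulate_vein("midvein", nondim_reduced, p, a0=a_s,
                              tau_s0=1.0, duration=100 * 50.0, a_min=0.01)
        assert tr.attrs["outcome"] == "completed"
        assert abs(tr["a"].iloc[-1] - a_s) / a_s < 1e-8

    def test_below_saddle_vanishes(self, nondim_reduced):
        p = params(t_adapt=50.0, t_delay=5.0)
        a_u = vf.reduced_fixed_points(nondim_reduced, p)[1].radius
        tr = vf.simulate_vein("midvein", nondim_reduced, p, a0=0.97 * a_u,
                              tau_s0=1.0, duration=20000.0, a_min=0.01)
        assert tr.attrs["outcome"] == "vanished"

    def test_stable_spiral_is_clockwise(self, nondim_reduced):
        # complex eigenvalues near the stable point; (a, τs) loop circles
        # clockwise (negative shoelace area)
        p = params(t_adapt=60.0, t_delay=10.0)
        fp = vf.reduced_fixed_points(nondim_reduced, p)[2]
        assert abs(fp.eigenvalues[0].imag) > 0
        tr = vf.simulate_vein("midvein", nondim_reduced, p,
                              a0=1.12 * fp.radius, tau_s0=1.0,
                              duration=1200.0, a_min=0.01)
        assert loop_orientation(tr["a"], tr["tau_s"]) == "clockwise"

    def test_dangling_monotone_and_threshold(self):
        # overdamped regime (t_adapt >> 8 t_delay): monotone growth/shrink;
        # τ0 sets the growth-vs-vanish threshold
        rs = vf.ReducedSystem(length=1.0, eps=1.0, period=32.0 / 2.5,
                              coupling=1.0)
        # equilibrium radius a* = 32 L eps / (tau0 T) = beta/tau0-scaled
        p_grow = params(t_adapt=400.0, tau0=0.5, t_delay=10.0)  # a* = 5
        tr = vf.simulate_vein("dangling", rs, p_grow, a0=1.0, tau_s0=None,
                              duration=4000.0, a_min=0.05)
        a = tr["a"].to_numpy()
        t = tr["t"].to_numpy()
        post = a[t > 5 * p_grow.t_delay_s]
        grow_part = post[post < 0.95 * 5.0]
        assert np.all(np.diff(grow_part) > 0)          # monotone growth

        p_shrink = params(t_adapt=400.0, tau0=100.0, t_delay=10.0)  # a* tiny
        tr2 = vf.simulate_vein("dangling", rs, p_shrink, a0=1.0,
                               tau_s0=None, duration=8000.0, a_min=0.05)
        assert tr2.attrs["outcome"] == "vanished"
        a2 = tr2["a"].to_numpy()
        t2 = tr2["t"].to_numpy()
        post2 = a2[t2 > 5 * p_shrink.t_delay_s]
        assert np.all(np.diff(post2) < 0)              # monotone shrinkage

    def test_dangling_growth_hits_cap(self):
        rs = vf.ReducedSystem(length=1.0, eps=1.0, period=32.0 / 2.5,
                              coupling=1.0)
        p = vf.AdaptationParams(t_adapt_s=100.0, tau0=0.05, t_delay_s=5.0,
                                a_min_um=0.05, growth_cap_factor=3.0)
        tr = vf.simulate_vein("dangling", rs, p, a0=1.0, tau_s0=None,
                              duration=50000.0, a_min=0.05)
        assert tr.attrs["outcome"] == "grew_to_cap"

    def test_shrinking_trajectory_diversity(self):
        # two-positive-root regime near the saddle-node: both monotone and
        # single-maximum (non-monotone) shear histories among vanishing runs
        beta = 2.5
        c = 0.8 * 27 * beta**4 / 256
        rs = vf.ReducedSystem(length=1.0, eps=1.0, period=32.0 / beta,
                              coupling=c)
        p = params(t_adapt=200.0, t_delay=50.0)

        def shape(a0, ts0):
            tr = vf.simulate_vein("midvein", rs, p, a0=a0, tau_s0=ts0,
                                  duration=8000.0, a_min=0.05)
            if tr.attrs["outcome"] != "vanished":
                return None
            tau = tr["tau_fluid"].to_numpy()
            d = np.sign(np.diff(tau))
            d = d[d != 0]
            changes = int(np.sum(d[1:] != d[:-1]))
            maxima = int(np.sum((d[:-1] > 0) & (d[1:] < 0)))
            return changes, maxima

        assert shape(0.4, 0.3) == (0, 0)        # monotone decreasing shear
        assert shape(1.9, 0.1) == (1, 1)        # rises once, then falls

    def test_murray_consistency_on_convergence(self, nondim_reduced):
        # converged trajectory ends at <τ> = τs = τ0
        p = params(t_adapt=50.0, t_delay=5.0)
        fp = vf.reduced_fixed_points(nondim_reduced, p)[2]
        tr = vf.simulate_vein("midvein", nondim_reduced, p,
                              a0=1.3 * fp.radius, tau_s0=0.8,
                              duration=400 * 50.0, a_min=0.01)
        assert tr["tau_fluid"].iloc[-1] == pytest.approx(p.tau0, rel=1e-5)
        assert tr["tau_s"].iloc[-1] == pytest.approx(p.tau0, rel=1e-5)


class TestSimulateNetwork:
    def test_constructed_equilibrium_is_stationary(self):
        net, radii = make_random_net(seed=3, n=6, m=7)
        shear = time_averaged_shear(net, radii)
        p = {vid: vf.AdaptationParams(t_adapt_s=300.0,
                                      tau0=max(shear[vid], 1e-12),
                                      t_delay_s=60.0)
             for vid in net.veins}
        traj, ev = vf.simulate_network(net, p, duration=10 * 300.0, dt=6.0)
        assert len(ev) == 0
        for vid, grp in traj.groupby("vein_id"):
            a = grp["a_um"].to_numpy()
            assert abs(a[-1] - a[0]) / a[0] < 1e-6

    @staticmethod
    def _loop_net():
        net = vf.VeinNetwork()
        pos = {"n0": (0, 0), "n1": (3000, 0), "n2": (3000, 3000),
               "n3": (0, 3000), "m1": (1000, -500), "m2": (2000, -500)}
        for k, (x, y) in pos.items():
            net.add_node(k, float(x), float(y))
        E = [("b0", "n0", "n1", 3000, 40), ("b1", "n1", "n2", 3000, 40),
             ("b2", "n2", "n3", 3000, 40), ("b3", "n3", "n0", 3000, 40),
             ("l1", "n0", "m1", 1000, 15), ("l2", "m1", "m2", 1000, 15),
             ("l3", "m2", "n1", 1000, 15)]
        for k, u, v, L, a in E:
            net.add_vein(vf.VeinSegment(k, u, v, float(L), eps=0.05,
                                        period_s=100.0))
            net.veins[k].radii = vf.RadiusSeries(np.array([0.0, 6.0]),
                                                 np.full(2, float(a)))
        return net

    def test_loop_vanishes_from_the_middle(self):
        net = self._loop_net()
        radii = {vid: v.mean_radius_um() for vid, v in net.veins.items()}
        shear = time_averaged_shear(net, radii)
        p = {}
        for vid in net.veins:
            factor = 2.0 if vid.startswith("l") else 1.0  # loop destabilised
            p[vid] = vf.AdaptationParams(t_adapt_s=600.0,
                                         tau0=factor * shear[vid],
                                         t_delay_s=60.0, a_min_um=5.0)
        traj, ev = vf.simulate_network(net, p, duration=1500.0, dt=6.0)
        vanished = ev[ev.event == "vanished"]
        assert len(vanished) >= 1
        assert vanished.iloc[0]["vein_id"] == "l2"   # the middle segment

    @staticmethod
    def _parallel_net():
        net = vf.VeinNetwork()
        for k, (x, y) in {"A": (0, 0), "B": (1000, 0), "C": (500, 800),
                          "D": (500, -800)}.items():
            net.add_node(k, float(x), float(y))
        E = [("p1", "A", "B", 1000, 10.0), ("p2", "A", "B", 1000, 16.0),
             ("c1", "A", "C", 900, 13.0), ("c2", "C", "B", 900, 13.0),
             ("d1", "A", "D", 900, 13.0), ("d2", "D", "B", 900, 13.0)]
        for k, u, v, L, a in E:
            net.add_vein(vf.VeinSegment(k, u, v, float(L), eps=0.05,
                                        period_s=100.0))
            net.veins[k].radii = vf.RadiusSeries(np.array([0.0, 6.0]),
                                                 np.full(2, float(a)))
        return net

    def test_parallel_vein_with_larger_ratio_vanishes_first(self):
        net = self._parallel_net()
        radii = {vid: v.mean_radius_um() for vid, v in net.veins.items()}
        r1 = vf.relative_resistance(net, "p1", radii)
        r2 = vf.relative_resistance(net, "p2", radii)
        assert r1 > r2 > 0.1

        # common target shear for the competing pair, chosen between their
        # saddle-node thresholds: p1 has no finite fixed points, p2 does
        eq2 = vf.norton_equivalent(net, "p2", radii)
        mu = net.viscosity_mPas * MPAS
        c2 = 8 * mu * (1000 * UM) / (math.pi * eq2.network_resistance)
        beta = (256 * 1.5 * c2 / 27) ** 0.25
        tau0c = 32 * (1000 * UM) * 0.05 / (100.0 * beta)

        shear = time_averaged_shear(net, radii)
        p = {}
        for vid in net.veins:
            if vid in ("p1", "p2"):
                p[vid] = vf.AdaptationParams(t_adapt_s=600.0, tau0=tau0c,
                                             t_delay_s=60.0, a_min_um=5.0)
            else:
                p[vid] = vf.AdaptationParams(t_adapt_s=600.0,
                                             tau0=shear[vid],
                                             t_delay_s=60.0, a_min_um=5.0)
        traj, ev = vf.simulate_network(net, p, duration=3000.0, dt=6.0)
        vanished = list(ev[ev.event == "vanished"]["vein_id"])
        assert vanished == ["p1"]          # p1 goes, p2 persists
        final = traj[traj.time_s == traj.time_s.max()]
        assert float(final[final.vein_id == "p2"]["a_um"].iloc[0]) > 10.0
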