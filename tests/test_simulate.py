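"""Reaction-diffusion solver: exchange kinetics, conservation, oracles."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.special import i0e

import fdapsim as fs
from fdapsim.simulate import SimulationParams


class TestSteadyStateRate:
    @pytest.mark.parametrize("F0,G0,K,expected", [
        (100, 100, 0.06, 0.06),   # equal pools: k_pol = K_dep
        (0, 200, 0.1, 0.0),       # no filaments
        (150, 50, 0.1, 0.3),
    ])
    def test_detailed_balance_rate(self, F0, G0, K, expected):
        assert fs.steady_state_polymerization_rate(F0, G0, K) == \
            pytest.approx(expected)

    def test_empty_monomer_pool_rejected(self):
        with pytest.raises(ValueError):
            fs.steady_state_polymerization_rate(100, 0, 0.1)

    def test_params_derive_consistent_k_pol(self):
        p = SimulationParams(F0=150, K_dep=0.1)
        assert p.G0 == 50
        assert p.k_pol == pytest.approx(0.3)
        assert p.ratio == pytest.approx(50 / 150)


class TestConservationAndStationarity:
    def test_total_pa_constant_after_pulse(self, donly_d3):
        """Closed boundaries: whole-domain PA conserved to 0.1% over 25 s."""
        post = donly_d3.times >= 0
        tot = donly_d3.total_pa[post]
        assert np.max(np.abs(tot / tot[0] - 1)) < 1e-3

    def test_uniform_steady_split_is_stationary(self, coarse_sim):
        """PA initialized everywhere at the bulk G/F split stays constant."""
        sim = coarse_sim
        params = SimulationParams(D=3.0, F0=100.0, K_dep=0.06, t_pulse=0.0,
                                  t_post=2.0)
        n = sim.n
        g = np.full(n, params.G0)
        f = np.full(n, params.F0)
        lam = params.k_pol + params.K_dep
        for _, dt in sim.stepping.steps(0.0, 2.0):
            g = sim._solve_diffusion(g, params.D, dt)
            p = g + f
            g_eq = (params.K_dep / lam) * p
            g = g_eq + (g - g_eq) * np.exp(-lam * dt)
            f = p - g
        assert np.allclose(g, params.G0, rtol=1e-9)
        assert np.allclose(f, params.F0, rtol=1e-9)

    def test_immobile_only_curve_stays_at_one(self, coarse_grid, roi):
        """G ~ 0 and K_dep = 0: nothing can leave the ROI."""
        params = SimulationParams(F0=199.9, K_dep=0.0, D=3.0, t_post=2.0)
        res = fs.simulate_photoactivation(params, coarse_grid, roi)
        curve = res.decay_curve()
        assert np.all(curve.values > 0.999)


class TestExchangeOracle:
    def test_d0_limit_matches_matrix_exponential(self, coarse_sim):
        """With D = 0 and a non-equilibrium start (all PA monomeric) the ROI
        composition follows the 2-state linear ODE closed form."""
        params = SimulationParams(D=0.0, F0=120.0, K_dep=0.08, t_pulse=0.0,
                                  t_post=5.0)
        n = coarse_sim.n
        g0 = np.zeros(n)
        g0[coarse_sim.roi_mask] = 1.0
        res = coarse_sim.run(params, initial_state=(g0, np.zeros(n)))
        A = np.array([[-params.k_pol, params.K_dep],
                      [params.k_pol, -params.K_dep]])
        for t in (0.5, 1.0, 2.5, 5.0):
            gf = expm(A * t) @ np.array([1.0, 0.0])
            i = np.argmin(np.abs(res.times - t))
            assert res.roi_mean_g[i] == pytest.approx(gf[0], abs=1e-4)
            assert res.roi_mean[i] == pytest.approx(gf.sum(), abs=1e-4)
        # total PA in the ROI is exactly conserved when nothing diffuses
        assert np.allclose(res.roi_mean, 1.0, atol=1e-12)


class TestFreeDiffusionOracle:
    def test_early_retention_matches_analytic_2d_solution(self):
        """Flat slab + instantaneous disc: solver vs Gaussian-convolution
        closed form (radial Bessel integral), within 2%."""
        geom = fs.make_round_cell(8.0, 0.6, 0.6)  # flat slab, z-uniform
        roi = fs.ROISpec(center=(0.0, 0.0), radius=1.0)
        grid = fs.voxelize(geom, 0.1, half_cell=True, spacing_z=0.3, roi=roi)
        sim = fs.Simulator(grid, roi)
        D, a = 3.0, 1.0
        # instantaneous activation: unit concentration in a sharp disc
        # defined at voxel centers (matching the analytic initial condition)
        pts_all = grid.interior_points()
        sharp = np.hypot(pts_all[:, 0], pts_all[:, 1]) <= a
        g = np.zeros(sim.n)
        g[sharp] = 1.0
        checks = {0.05: None, 0.1: None, 0.2: None}
        t = 0.0
        for _, dt in sim.stepping.steps(0.0, 0.2):
            g = sim._solve_diffusion(g, D, dt)
            t += dt
            for tt in checks:
                if checks[tt] is None and t >= tt - 1e-9:
                    checks[tt] = g[sharp].mean()

        r = np.hypot(pts_all[sharp, 0], pts_all[sharp, 1])

        def analytic_mean(t):
            # c(r,t) = int_0^a r'/(2Dt) exp(-(r^2+r'^2)/4Dt) I0(rr'/2Dt) dr'
            rp = np.linspace(0, a, 400)[None, :]
            rr = r[:, None]
            z = rr * rp / (2 * D * t)
            integ = rp / (2 * D * t) * np.exp(
                -((rr - rp) ** 2) / (4 * D * t)) * i0e(z)
            return np.trapezoid(integ, rp[0], axis=1).mean()

        for tt, measured in checks.items():
            assert measured == pytest.approx(analytic_mean(tt), rel=0.02)


class TestCurveProperties:
    def test_normalized_curve_is_one_at_t_norm(self, donly_d3):
        c = donly_d3.decay_curve()
        assert c.value_at(0.035) == pytest.approx(1.0)
        assert c.t_norm == 0.035

    def test_decay_is_monotone_non_increasing(self, donly_d3):
        c = donly_d3.decay_curve()
        assert np.all(np.diff(c.values[c.times >= 0.035]) < 1e-3)

    def test_higher_kdep_decays_at_or_below(self, coarse_sim):
        curves = {}
        for K in (0.02, 0.1):
            params = SimulationParams(D=3.0, F0=100.0, K_dep=K, t_post=10.0)
            curves[K] = coarse_sim.run(params).decay_curve()
        fast, slow = curves[0.1], curves[0.02]
        ts = np.linspace(0.05, 10, 100)
        assert np.all(fast.value_at(ts) <= slow.value_at(ts) + 1e-3)

    def test_higher_g_fraction_decays_faster_early(self, coarse_sim):
        curves = {}
        for F in (60.0, 140.0):
            params = SimulationParams(D=3.0, F0=F, K_dep=0.06, t_post=3.0)
            curves[F] = coarse_sim.run(params).decay_curve()
        ts = np.linspace(0.05, 2.0, 50)
        assert np.all(curves[60.0].value_at(ts) <=
                      curves[140.0].value_at(ts) + 1e-3)


class TestNormalization:
    def test_constant_curve_normalizes_to_one(self):
        c = fs.normalize_curve(np.array([0.0, 1.0, 2.0]),
                               0.035, values=np.array([5.0, 5.0, 5.0]))
        assert np.allclose(c.values, 1.0)

    def test_two_point_example(self):
        c = fs.DecayCurve(np.array([0.035, 1.0]), np.array([4.0, 2.0]))
        n = fs.normalize_curve(c, 0.035)
        assert np.allclose(n.values, [1.0, 0.5])

    def test_t_norm_between_samples_interpolates(self):
        c = fs.DecayCurve(np.array([0.0, 0.07]), np.array([2.0, 6.0]))
        n = fs.normalize_curve(c, 0.035)   # interpolated normalizer = 4
        assert np.allclose(n.values, [0.5, 1.5])

    def test_nonpositive_normalizer_rejected(self):
        c = fs.DecayCurve(np.array([0.0, 1.0]), np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            fs.normalize_curve(c, 0.5)


class TestRoiMean:
    def test_uniform_field_returns_concentration(self, coarse_sim):
        n = coarse_sim.n
        snaps = [(0.0, np.full(n, 2.0), np.full(n, 1.5))]
        ts, vals = fs.roi_mean_timeseries(snaps, coarse_sim.roi_mask)
        assert vals[0] == pytest.approx(3.5)

    def test_pa_outside_roi_reads_zero(self, coarse_sim):
        n = coarse_sim.n
        g = np.ones(n)
        g[coarse_sim.roi_mask] = 0.0
        ts, vals = fs.roi_mean_timeseries([(0.0, g, np.zeros(n))],
                                          coarse_sim.roi_mask)
        assert vals[0] == 0.0

    def test_checker_field_matches_direct_summation(self, coarse_sim):
        rng = np.random.default_rng(1)
        g = rng.random(coarse_sim.n)
        f = rng.random(coarse_sim.n)
        _, vals = fs.roi_mean_timeseries([(0.0, g, f)], coarse_sim.roi_mask)
        m = coarse_sim.roi_mask
        assert vals[0] == pytest.approx((g[m] + f[m]).sum() / m.sum())

    def test_empty_roi_rejected(self, coarse_sim):
        with pytest.raises(ValueError):
            fs.roi_mean_timeseries([(0.0, np.ones(3), np.ones(3))],
                                   np.zeros(3, dtype=bool))


class TestDelayLoss:
    def test_zero_delay_zero_loss(self, coarse_grid, roi):
        assert fs.delay_loss(3.0, 0.0, coarse_grid, roi) == 0.0

    def test_loss_increases_with_delay(self, donly_d3, coarse_grid, roi):
        losses = [fs.delay_loss(3.0, d, coarse_grid, roi, result=donly_d3)
                  for d in (0.02, 0.05, 0.1, 0.2)]
        assert np.all(np.diff(losses) > 0)

    def test_negative_delay_rejected(self, coarse_grid, roi):
        with pytest.raises(ValueError):
            fs.delay_loss(3.0, -0.1, coarse_grid, roi)


class TestAxonGeometryEffects:
    def test_axon_length_does_not_change_decay(self):
        """Doubling the axon length leaves the mid-axon ROI curve unchanged
        (the far ends never matter on this time scale)."""
        curves = []
        for L in (40.0, 80.0):
            geom, roi_ax = fs.make_axon(L, 0.5, 0.5)
            grid = fs.voxelize(geom, 0.25, half_cell=True, spacing_z=0.125,
                               roi=roi_ax)
            res = fs.simulate_diffusion_only(3.0, grid, roi_ax, t_post=10.0)
            curves.append(res.decay_curve())
        ts = np.linspace(0.05, 10, 100)
        diff = np.abs(curves[0].value_at(ts) - curves[1].value_at(ts))
        assert diff.max() < 5e-3
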