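import numpy as np
import pytest

from pulsepkpd import structural_models as sm


class TestBuildingBlocks:
    def test_circadian_factor_peak_trough_and_zero(self):
        assert sm.circadian_factor(17.3, 0.168, 17.3, 24.0) == pytest.approx(0.168)
        assert sm.circadian_factor(17.3 + 12, 0.168, 17.3, 24.0) == pytest.approx(-0.168)
        assert np.all(sm.circadian_factor(np.arange(24.0), 0.0, 5.0, 24.0) == 0.0)

    def test_circadian_factor_periodicity(self):
        t = np.linspace(0, 24, 49)
        a = sm.circadian_factor(t, 0.095, 10.2, 12.0)
        b = sm.circadian_factor(t + 36.0, 0.095, 10.2, 12.0)
        np.testing.assert_allclose(a, b, atol=1e-12)

    @pytest.mark.parametrize("exposure,slope,expected", [
        (0.0, 2.73, 0.0),
        (1.0 / 2.73, 2.73, 0.5),
        (1.0, 2.73, 2.73 / 3.73),
    ])
    def test_exposure_inhibition_values(self, exposure, slope, expected):
        assert sm.exposure_inhibition(exposure, slope) == pytest.approx(expected)

    def test_exposure_inhibition_monotone_and_bounded(self):
        x = np.linspace(0, 50, 200)
        y = sm.exposure_inhibition(x, 2.73)
        assert np.all(np.diff(y) > 0) and y[0] == 0.0 and y[-1] < 1.0

    def test_exposure_inhibition_rejects_negative(self):
        with pytest.raises(ValueError):
            sm.exposure_inhibition(-0.1, 2.73)

    @pytest.mark.parametrize("c,emax,expected", [
        (0.0, -0.648, 1.0),
        (0.609, -0.648, 1.0 - 0.648 / 2.0),
        (1e9, -0.91, pytest.approx(0.09, abs=1e-6)),
    ])
    def test_emax_factor_algebra(self, c, emax, expected):
        assert sm.emax_factor(c, emax, 0.609) == pytest.approx(expected)

    def test_emax_factor_monotone_nonincreasing(self):
        c = np.linspace(0, 20, 100)
        f = sm.emax_factor(c, -0.648, 0.609)
        assert np.all(np.diff(f) <= 0) and np.all((f > 0) & (f <= 1))


class TestEffectCompartment:
    def test_zero_plasma_gives_zero_effect_site(self):
        drug = sm.DrugInput.zero(0.0, 24.0)
        ce = sm.effect_compartment(drug, 1.25, np.linspace(0, 24, 49))
        np.testing.assert_allclose(ce, 0.0, atol=1e-12)

    def test_first_order_equilibration_half_time(self):
        # constant plasma: Ce(t) = Cp (1 - exp(-ke0 t)); half at ln2/ke0
        drug = sm.DrugInput(np.array([0.0, 48.0]), np.array([4.0, 4.0]))
        ke0 = 1.25
        t_half = np.log(2) / ke0
        ce = sm.effect_compartment(drug, ke0, np.array([t_half, 3.0 / ke0]))
        assert ce[0] == pytest.approx(2.0, rel=1e-3)
        assert ce[1] == pytest.approx(4.0 * (1 - np.exp(-3)), rel=1e-3)


class TestCumulativeExposure:
    def test_rectangle_with_unit_conversion(self):
        drug = sm.DrugInput(np.array([0.0, 10.0]), np.array([1.0, 1.0]))
        assert sm.cumulative_exposure(drug, 10.0) == pytest.approx(0.01)
        assert sm.cumulative_exposure(drug, 0.0) == 0.0

    def test_piecewise_linear_matches_hand_trapezoid(self):
        drug = sm.DrugInput(np.array([0.0, 2.0, 6.0]), np.array([0.0, 3.0, 1.0]))
        # trapezoids: 0.5*2*3 + 0.5*4*(3+1) = 3 + 8 = 11 µg·h/L
        assert sm.cumulative_exposure(drug, 6.0) == pytest.approx(11e-3)

    def test_nondecreasing(self):
        rng = np.random.default_rng(0)
        drug = sm.DrugInput(np.linspace(0, 24, 100), rng.uniform(0, 5, 100))
        vals = sm.cumulative_exposure(drug, np.linspace(0, 30, 60))
        assert np.all(np.diff(vals) >= -1e-15)


class TestGH:
    def setup_method(self):
        self.p = sm.GHParams()
        self.times = np.arange(0.0, 12.0 + 1e-9, 1.0 / 3.0)
        self.pt = np.array([1.0, 4.0, 8.5])
        self.pm = np.array([1.5, 0.8, 2.5])

    def test_no_pulses_no_drug_is_constant_baseline(self):
        c = sm.gh_concentration(self.p, [], None, None, self.times)
        np.testing.assert_allclose(c, 0.056, atol=1e-12)

    def test_single_pulse_mass_balance(self):
        tt = np.arange(-2, 40, 0.005)
        c = sm.gh_concentration(self.p, [3.0], [1.7], None, tt)
        integral = self.p.k_el * np.trapezoid(c - self.p.baseline, tt)
        assert integral == pytest.approx(1.7, rel=1e-4)

    def test_ode_matches_analytic_superposition(self):
        ca = sm.gh_concentration(self.p, self.pt, self.pm, None, self.times)
        co = sm.gh_concentration(self.p, self.pt, self.pm, None, self.times,
                                 method="ode", rtol=1e-10, atol=1e-12)
        assert np.max(np.abs(ca - co)) < 1e-6

    def test_linear_superposition_of_pulses(self):
        total = sm.gh_concentration(self.p, self.pt, self.pm, None, self.times)
        parts = sum(sm.gh_concentration(self.p, [t], [m], None, self.times)
                    - self.p.baseline
                    for t, m in zip(self.pt, self.pm))
        np.testing.assert_allclose(total, self.p.baseline + parts, rtol=1e-10)

    def test_drug_reduces_pulse_mass_monotonically(self):
        t_grid = np.arange(0.0, 14.0, 0.1)
        resp = []
        for dose_scale in (0.0, 1.0, 3.0):
            drug = sm.DrugInput(t_grid, dose_scale * np.full(t_grid.size, 2.0),
                                first_dose_time=0.0) if dose_scale else None
            c = sm.gh_concentration(self.p, self.pt, self.pm, drug, self.times)
            resp.append(np.trapezoid(c - self.p.baseline, self.times))
        assert resp[0] > resp[1] > resp[2] > 0

    def test_kernel_is_nonnegative_and_stable_far_from_pulse(self):
        u = np.linspace(-50, 200, 5000)
        k = sm.gh_pulse_kernel(u, 0.184, 3.6)
        assert np.all(np.isfinite(k)) and np.all(k >= 0)
        assert k[0] == pytest.approx(0.0, abs=1e-30)
        assert k[-1] == pytest.approx(0.0, abs=1e-30)


class TestPRL:
    def test_steady_state_without_circadian_or_drug(self):
        p = sm.PRLParams(amp24=0.0, amp12=0.0)
        c = sm.prl_concentration(p, None, 0.0, np.array([50.0, 100.0]))
        np.testing.assert_allclose(c, 13.3 / 1.25, rtol=1e-6)

    def test_exact_integrator_matches_adaptive_solver(self):
        p = sm.PRLParams()
        t = np.arange(0.0, 14.0 + 1e-9, 1.0 / 3.0)
        grid = np.arange(0.0, 40.0, 0.1)
        drug = sm.DrugInput(grid, 5 * np.exp(-0.2 * grid) * (1 - np.exp(-grid)),
                            first_dose_time=0.0)
        fast = sm.prl_concentration(p, drug, 2.0, t + 2.0)
        slow = sm.prl_concentration_ode(p, drug, 2.0, t + 2.0,
                                        rtol=1e-9, atol=1e-11)
        assert np.max(np.abs(fast / slow - 1)) < 1e-3

    def test_drug_free_solution_is_24h_periodic_after_run_in(self):
        p = sm.PRLParams()
        t1 = np.linspace(48.0, 72.0, 97)
        c1 = sm.prl_concentration(p, None, 0.0, t1, run_in=48.0)
        c2 = sm.prl_concentration(p, None, 0.0, t1 + 24.0, run_in=48.0)
        assert np.max(np.abs(c2 / c1 - 1)) < 1e-3

    def test_half_maximal_release_inhibition_at_ec50(self):
        # constant plasma drug at EC50 halves the release factor
        # (1 + Emax/2 = 0.545 at Emax = -0.91); plasma drops by that factor
        # on its fast timescale (the slow ~90 h pool barely moves), which is
        # the transient suppression-and-return the analysis describes
        p = sm.PRLParams(amp24=0.0, amp12=0.0, slope=0.0)
        grid = np.array([100.0, 300.0])
        drug = sm.DrugInput(grid, np.full(2, p.ec50), first_dose_time=100.0)
        c = sm.prl_concentration(p, drug, 0.0, np.array([105.0, 150.0]),
                                 run_in=48.0)
        assert c[0] == pytest.approx((13.3 / 1.25) * (1 - 0.91 / 2), rel=0.03)
        # ... and then creeps back up as the pool refills
        assert c[1] > c[0]

    def test_bathyphase_in_the_morning(self):
        # within the sampled part of the day (6 a.m. - 8 p.m.), release is
        # lowest in the morning and higher through the afternoon
        p = sm.PRLParams()
        clock = np.linspace(0.0, 14.0, 141)  # normalized: 0 = 6 a.m.
        kr = sm._prl_release_rate(p, clock, np.zeros_like(clock))
        wall = clock + 6.0
        wall_min = wall[np.argmin(kr)]
        assert 6.0 <= wall_min <= 12.0
        morning = kr[(wall >= 6) & (wall < 12)].mean()
        afternoon = kr[(wall >= 12) & (wall <= 18)].mean()
        assert afternoon > morning

    def test_amplitude_sum_invariant_enforced(self):
        with pytest.raises(ValueError):
            sm.PRLParams(amp24=0.7, amp12=0.4).validated()

    def test_mass_conservation_at_steady_state(self):
        # production k_s*T equals elimination k_el * integral(C) over a window
        p = sm.PRLParams(amp24=0.0, amp12=0.0)
        t = np.arange(100.0, 124.0, 0.01)
        c = sm.prl_concentration(p, None, 0.0, t)
        produced = p.k_s * (t[-1] - t[0])
        eliminated = p.k_el * np.trapezoid(c, t)
        assert eliminated == pytest.approx(produced, rel=1e-6)
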