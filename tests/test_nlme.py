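import math

import numpy as np
import pytest
from scipy import stats

from pulsepkpd import nlme
from pulsepkpd import trial_synth as ts

from conftest import make_linear_subjects


class TestOFV:
    def test_matches_closed_form_marginal_likelihood(self, linear_model,
                                                     linear_pset, rng):
        # y = mu + eta + eps, one obs per subject: marginal is
        # N(mu, omega2 + sigma2); the Laplace objective is exact here
        y = rng.normal(2.0, 1.0, 15)
        subs = make_linear_subjects(y)
        val = nlme.ofv(linear_model, subs, linear_pset)
        closed = sum((yi - 2.0) ** 2 / 0.8 + math.log(2 * math.pi * 0.8)
                     for yi in y)
        assert val == pytest.approx(closed, abs=1e-6)

    def test_invariant_to_subject_ordering(self, linear_model, linear_pset, rng):
        y = rng.normal(2.0, 1.0, 9)
        subs = make_linear_subjects(y)
        assert nlme.ofv(linear_model, subs, linear_pset) == pytest.approx(
            nlme.ofv(linear_model, subs[::-1], linear_pset), abs=1e-9)

    def test_zero_variance_reduces_to_residual_likelihood(self, linear_model,
                                                          rng):
        y = rng.normal(2.0, 0.5, 8)
        pset = nlme.ParameterSet({"mu": nlme.Theta(2.0, "identity")},
                                 omega2={"mu": 0.0}, sigma2=0.3,
                                 error_model="additive")
        val = nlme.ofv(linear_model, make_linear_subjects(y), pset)
        closed = sum((yi - 2.0) ** 2 / 0.3 + math.log(2 * math.pi * 0.3)
                     for yi in y)
        assert val == pytest.approx(closed, abs=1e-9)

    def test_gh_model_ofv_deterministic(self, small_gh_trial):
        subs = nlme.subjects_from_trial(small_gh_trial, "GH")
        m = nlme.GHModel()
        p = nlme.GHModel.default_parameters()
        assert nlme.ofv(m, subs, p) == pytest.approx(nlme.ofv(m, subs, p),
                                                     abs=1e-6)


class TestFit:
    def test_recovers_mean_of_linear_model(self, linear_model, rng):
        y = rng.normal(3.0, math.sqrt(0.5 + 0.1), 60)
        subs = make_linear_subjects(y)
        start = nlme.ParameterSet({"mu": nlme.Theta(1.0, "identity")},
                                  omega2={"mu": 0.5}, sigma2=0.1,
                                  error_model="additive",
                                  fixed_omega2={"mu"}, sigma2_fixed=True)
        res = nlme.fit(linear_model, subs, start)
        assert res.params.theta["mu"].value == pytest.approx(y.mean(), abs=0.02)

    def test_self_consistency_with_tiny_variances(self):
        # GH data simulated with negligible noise: the fit stays at the
        # generating values
        gh = ts.GHPopulation(omega2_baseline=1e-4, omega2_width=1e-4,
                             omega2_k_el=1e-4, omega2_amplitude_n=1e-4,
                             bov2_width=0.0, bov2_k_el=0.0, sigma2=1e-4)
        trial = ts.simulate_trial([("placebo", 0, 3)], gh_pop=gh, seed=8,
                                  hormones=("GH",))
        subs = nlme.subjects_from_trial(trial, "GH")
        start = nlme.GHModel.default_parameters()
        start.omega2 = {"baseline": 1e-4, "width": 1e-4, "k_el": 1e-4,
                        "amplitude_n": 1e-4}
        start.bov2 = {}
        start.sigma2 = 1e-4
        pset = start.with_all_fixed(except_names=("width", "k_el"))
        res = nlme.fit(nlme.GHModel(), subs, pset, maxfev=400)
        assert res.params.theta["width"].value == pytest.approx(0.184, rel=0.02)
        assert res.params.theta["k_el"].value == pytest.approx(3.6, rel=0.02)

    def test_missing_drug_effect_detected_by_lrt(self):
        # omitting the drug effect on drug-affected data costs > 6.64 OFV
        trial = ts.simulate_trial([("1.5 mg s.a.d.", 8, 0),
                                   ("1.0 mg b.i.d.", 8, 0)], seed=9,
                                  hormones=("GH",))
        subs = nlme.subjects_from_trial(trial, "GH")
        m = nlme.GHModel()
        true_pset = nlme.GHModel.default_parameters()
        no_drug = true_pset.copy()
        no_drug.theta["emax"].value = -1e-10
        full = nlme.ofv(m, subs, true_pset)
        reduced = nlme.ofv(m, subs, no_drug)
        cmp_ = nlme.lrt(reduced, full, df=2)
        assert cmp_.significant and cmp_.delta_ofv > 6.64


class TestLRT:
    def test_critical_value_reproduces_printed_threshold(self):
        cmp_ = nlme.lrt(100.0, 95.0, df=1, alpha=0.01)
        assert round(cmp_.critical_value, 2) == pytest.approx(6.63, abs=0.011)
        assert abs(cmp_.critical_value - 6.64) < 0.01

    @pytest.mark.parametrize("df", [1, 2, 3, 4, 5])
    def test_critical_values_match_chi_square_quantiles(self, df):
        cmp_ = nlme.lrt(10.0, 1.0, df=df, alpha=0.01)
        assert cmp_.critical_value == pytest.approx(
            stats.chi2.ppf(0.99, df), abs=1e-4)

    def test_55_point_drop_is_significant(self):
        assert nlme.lrt(100.0, 44.6, df=2).significant

    def test_zero_drop_is_not(self):
        cmp_ = nlme.lrt(50.0, 50.0, df=1)
        assert not cmp_.significant

    def test_negative_drop_warns(self):
        cmp_ = nlme.lrt(50.0, 51.0, df=1)
        assert cmp_.warning != ""

    def test_df_zero_rejected(self):
        with pytest.raises(ValueError):
            nlme.lrt(1.0, 0.0, df=0)


class TestCovarianceStep:
    def test_linear_mixed_model_matches_information_matrix(self, linear_model,
                                                           rng):
        # SE(mu) for y_i ~ N(mu, omega2+sigma2) is sqrt((omega2+sigma2)/n)
        n = 40
        y = rng.normal(2.0, math.sqrt(0.8), n)
        subs = make_linear_subjects(y)
        pset = nlme.ParameterSet({"mu": nlme.Theta(float(y.mean()), "identity")},
                                 omega2={"mu": 0.5}, sigma2=0.3,
                                 error_model="additive",
                                 fixed_omega2={"mu"}, sigma2_fixed=True)
        res = nlme.fit(linear_model, subs, pset)
        res = nlme.covariance_step(linear_model, subs, res)
        assert res.cov_status == "ok"
        assert res.se["mu"] == pytest.approx(math.sqrt(0.8 / n), rel=0.01)
        assert res.condition_number == pytest.approx(1.0)

    def test_failure_reported_not_raised(self, linear_model, rng):
        # a flat direction (duplicate information) must mark the step failed
        y = rng.normal(2.0, 1.0, 5)
        subs = make_linear_subjects(y)
        pset = nlme.ParameterSet(
            {"mu": nlme.Theta(2.0, "identity")},
            omega2={"mu": 1e6}, sigma2=1e6, error_model="additive")
        res = nlme.FitResult(pset, 0.0, ["mu"], {}, True, 1)
        out = nlme.covariance_step(linear_model, subs, res)
        assert out.cov_status.startswith(("ok", "failed"))


class TestBootstrap:
    def test_identity_replicate_reproduces_fit(self, linear_model, rng):
        y = rng.normal(2.0, 1.0, 12)
        subs = make_linear_subjects(y)
        pset = nlme.ParameterSet({"mu": nlme.Theta(float(y.mean()), "identity")},
                                 omega2={"mu": 0.5}, sigma2=0.3,
                                 error_model="additive",
                                 fixed_omega2={"mu"}, sigma2_fixed=True)
        res = nlme.fit(linear_model, subs, pset)
        boot = nlme.bootstrap(linear_model, subs, res, n_samples=1,
                              identity_first=True)
        assert boot.minimization_success == 1.0
        assert boot.medians["mu"] == pytest.approx(
            res.params.theta["mu"].value, abs=1e-4)

    def test_resampling_intervals_cover_truth(self, linear_model):
        rng = np.random.default_rng(77)  # dedicated stream: deterministic draw
        y = rng.normal(2.0, math.sqrt(0.8), 40)
        subs = make_linear_subjects(y)
        pset = nlme.ParameterSet({"mu": nlme.Theta(float(y.mean()), "identity")},
                                 omega2={"mu": 0.5}, sigma2=0.3,
                                 error_model="additive",
                                 fixed_omega2={"mu"}, sigma2_fixed=True)
        res = nlme.fit(linear_model, subs, pset)
        boot = nlme.bootstrap(linear_model, subs, res, n_samples=30, seed=4)
        assert boot.ci_low["mu"] < 2.0 < boot.ci_high["mu"]

    def test_n_samples_validated(self, linear_model):
        with pytest.raises(ValueError):
            nlme.bootstrap(linear_model, [], None, n_samples=0)


class TestTransforms:
    def test_round_trip(self):
        for t in (nlme.Theta(3.6, "log"), nlme.Theta(-0.648, "logit_neg"),
                  nlme.Theta(17.3, "identity")):
            assert t.decoded(t.encode()) == pytest.approx(t.value, rel=1e-12)

    def test_reparameterization_invariance_of_minimum(self, linear_model, rng):
        # fitting mu on the identity scale vs a rescaled identity scale
        # reaches the same OFV
        y = rng.normal(2.0, 1.0, 25)
        subs = make_linear_subjects(np.abs(y) + 0.5)
        base = dict(omega2={"mu": 0.5}, sigma2=0.3, error_model="additive",
                    fixed_omega2={"mu"}, sigma2_fixed=True)
        r1 = nlme.fit(linear_model,
                      subs, nlme.ParameterSet({"mu": nlme.Theta(1.5, "identity")},
                                              **base))
        r2 = nlme.fit(linear_model,
                      subs, nlme.ParameterSet({"mu": nlme.Theta(1.5, "log")},
                                              **base))
        assert r1.ofv == pytest.approx(r2.ofv, abs=0.1)
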