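import numpy as np
import pandas as pd
import pytest

from pulsepkpd import diagnostics as dg
from pulsepkpd import nlme
from pulsepkpd import trial_synth as ts

from conftest import make_linear_subjects


@pytest.fixture(scope="module")
def prl_fit():
    """Model-true PRL setting: simulate at the published vector and evaluate
    diagnostics at the generating parameters."""
    trial = ts.simulate_trial([("placebo", 0, 4), ("1.5 mg s.a.d.", 4, 0)],
                              seed=31, hormones=("PRL",))
    subjects = nlme.subjects_from_trial(trial, "PRL")
    model = nlme.PRLModel()
    pset = nlme.PRLModel.default_parameters()
    fit = nlme.FitResult(pset, 0.0, [], nlme.ebes(model, subjects, pset),
                         True, 0)
    return model, subjects, fit


class TestCWRESI:
    def test_calibrated_on_model_true_data(self, prl_fit):
        model, subjects, fit = prl_fit
        rt = dg.cwresi(model, subjects, fit)
        assert rt.fraction_outside(2.0) < 0.10
        assert abs(rt.table.CWRESI.mean()) < 0.2
        assert 0.7 < rt.table.CWRESI.std() < 1.3

    def test_misspecified_drug_effect_biases_residuals(self, prl_fit):
        model, subjects, _ = prl_fit
        wrong = nlme.PRLModel.default_parameters()
        wrong.theta["emax"].value = -1e-9  # pretend there is no drug effect
        fit = nlme.FitResult(wrong, 0.0, [],
                             nlme.ebes(model, subjects, wrong), True, 0)
        rt = dg.cwresi(model, subjects, fit)
        active = rt.table[rt.table.ID.isin(
            [s.id for s in subjects if s.drug is not None])]
        treated = active[active.TAD > 0]
        pre = active[active.TAD <= 0]
        # suppressed observations sit below the drug-free prediction: the
        # treatment-window residual mean is negative (part of the misfit is
        # absorbed by the empirical Bayes estimates, so the bias is modest)
        assert treated.CWRESI.mean() < -0.1
        assert treated.CWRESI.mean() < pre.CWRESI.mean()

    def test_invariant_to_subject_relabeling(self, prl_fit):
        model, subjects, fit = prl_fit
        rt1 = dg.cwresi(model, subjects, fit)
        rt2 = dg.cwresi(model, subjects[::-1], fit)
        a = rt1.table.sort_values(["ID", "TAD"]).CWRESI.to_numpy()
        b = rt2.table.sort_values(["ID", "TAD"]).CWRESI.to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestNPDE:
    def test_same_seed_identical(self, prl_fit):
        model, subjects, fit = prl_fit
        r1 = dg.npde(model, subjects[:3], fit, n_sim=150, seed=5)
        r2 = dg.npde(model, subjects[:3], fit, n_sim=150, seed=5)
        np.testing.assert_array_equal(r1.table.NPDE, r2.table.NPDE)

    def test_boundary_ranks_are_finite(self, linear_model):
        # observation far below every simulation maps through the
        # 1/(2 n_sim) clamp to a finite value
        subs = make_linear_subjects([-50.0])
        pset = nlme.ParameterSet({"mu": nlme.Theta(0.0, "identity")},
                                 omega2={"mu": 0.5}, sigma2=0.3,
                                 error_model="additive")
        fit = nlme.FitResult(pset, 0.0, [], {}, True, 0)
        res = dg.npde(linear_model, subs, fit, n_sim=200, seed=1)
        v = res.table.NPDE.to_numpy()
        assert np.isfinite(v).all()
        from scipy import stats
        assert v[0] == pytest.approx(stats.norm.ppf(1 / 400), abs=1e-9)

    def test_calibrated_per_day_on_model_true_data(self, prl_fit):
        model, subjects, fit = prl_fit
        res = dg.npde(model, subjects, fit, n_sim=300, seed=2)
        for _, row in res.summary.iterrows():
            assert abs(row["mean"]) < 0.25
            assert 0.6 < row["var"] < 1.4

    def test_minimum_simulations_enforced(self, prl_fit):
        model, subjects, fit = prl_fit
        with pytest.raises(ValueError):
            dg.npde(model, subjects, fit, n_sim=50)


class TestPCVPC:
    def test_gh_request_refused(self, small_gh_trial):
        subjects = nlme.subjects_from_trial(small_gh_trial, "GH")
        model = nlme.GHModel()
        pset = nlme.GHModel.default_parameters()
        fit = nlme.FitResult(pset, 0.0, [], {}, True, 0)
        with pytest.raises(dg.UnsupportedDiagnosticError,
                           match="pcVPC unsupported for pulsatile GH"):
            dg.pcvpc(model, subjects, fit)

    def test_single_bin_correction_constant(self, prl_fit):
        model, subjects, fit = prl_fit
        res = dg.pcvpc(model, subjects, fit, bins=1, n_sim=60, seed=3)
        assert len(res.bins) == 1

    def test_observed_percentiles_inside_bands_mostly(self, prl_fit):
        model, subjects, fit = prl_fit
        res = dg.pcvpc(model, subjects, fit, bins=8, n_sim=120, seed=4)
        assert res.coverage() >= 0.75  # small-sample smoke check

    def test_correction_is_identity_without_iiv(self, linear_model, rng):
        # all subjects share the population prediction -> correction factor 1
        subs = make_linear_subjects(rng.normal(5.0, 0.3, 12))

        class M(type(linear_model)):
            hormone = "PRL"
        m = M()
        pset = nlme.ParameterSet({"mu": nlme.Theta(5.0, "identity")},
                                 omega2={}, sigma2=0.09,
                                 error_model="additive")
        fit = nlme.FitResult(pset, 0.0, [], {}, True, 0)
        res = dg.pcvpc(m, subs, fit, bins=1, n_sim=80, seed=5)
        row = res.bins.iloc[0]
        ys = np.array([s.y[0] for s in subs])
        assert row.obs_p50 == pytest.approx(np.median(ys), rel=1e-9)


class TestShrinkage:
    def test_all_zero_ebes_give_full_shrinkage(self):
        pset = nlme.PRLModel.default_parameters()
        meta = [("iiv", "k_s"), ("iiv", "amp24"), ("iiv", "amp12")]
        ebes = {i: (np.zeros(3), meta) for i in range(1, 9)}
        fit = nlme.FitResult(pset, 0.0, [], ebes, True, 0)
        out = dg.shrinkage(fit)
        assert all(v == pytest.approx(100.0) for v in out.values())

    def test_prior_distributed_ebes_have_low_shrinkage(self, rng):
        pset = nlme.PRLModel.default_parameters()
        meta = [("iiv", "k_s")]
        draws = rng.normal(0, np.sqrt(pset.omega2["k_s"]), 400)
        ebes = {i: (np.array([d]), meta) for i, d in enumerate(draws)}
        fit = nlme.FitResult(pset, 0.0, [], ebes, True, 0)
        assert abs(dg.shrinkage(fit)["k_s"]) < 10.0

    def test_sparse_design_shrinks_more_than_rich(self):
        # 1-obs-per-subject PRL design vs the full sampling grid
        model = nlme.PRLModel()
        pset = nlme.PRLModel.default_parameters()
        trial = ts.simulate_trial([("placebo", 0, 8)], seed=41,
                                  hormones=("PRL",))
        rich = nlme.subjects_from_trial(trial, "PRL")
        sparse = [nlme.SubjectData(id=s.id, times=s.times[:1], y=s.y[:1],
                                   occ=s.occ[:1]) for s in rich]
        f_rich = nlme.FitResult(pset, 0.0, [],
                                nlme.ebes(model, rich, pset), True, 0)
        f_sparse = nlme.FitResult(pset, 0.0, [],
                                  nlme.ebes(model, sparse, pset), True, 0)
        s_rich = dg.shrinkage(f_rich)["k_s"]
        s_sparse = dg.shrinkage(f_sparse)["k_s"]
        assert s_sparse > s_rich


class TestCovariateScreen:
    @staticmethod
    def _fit_with_ebes(ebe_by_id):
        pset = nlme.PRLModel.default_parameters()
        meta = [("iiv", "k_s")]
        ebes = {i: (np.array([v]), meta) for i, v in ebe_by_id.items()}
        return nlme.FitResult(pset, 0.0, [], ebes, True, 0)

    def test_exact_linear_relation_flagged(self):
        ids = range(1, 31)
        ebes = {i: 0.02 * i - 0.3 for i in ids}
        fit = self._fit_with_ebes(ebes)
        cov = pd.DataFrame({"weight": [70 + i for i in ids]},
                           index=list(ids))
        res = dg.covariate_screen(fit, cov)
        assert ("k_s", "weight") in res.flagged
        assert res.r2.r2.iloc[0] == pytest.approx(1.0)

    def test_independent_covariate_not_flagged(self, rng):
        ids = range(1, 61)
        ebes = {i: rng.normal(0, 0.25) for i in ids}
        fit = self._fit_with_ebes(ebes)
        cov = pd.DataFrame({"age": rng.normal(30, 8, 60)}, index=list(ids))
        res = dg.covariate_screen(fit, cov)
        assert res.flagged == []

    def test_constant_covariate_skipped_with_note(self):
        ids = range(1, 11)
        fit = self._fit_with_ebes({i: 0.1 * i for i in ids})
        cov = pd.DataFrame({"height": [180.0] * 10}, index=list(ids))
        res = dg.covariate_screen(fit, cov)
        assert res.flagged == []
        assert (res.r2.note == "constant covariate").any()

    def test_no_flags_gives_empty_stepping(self, rng):
        ids = range(1, 31)
        fit = self._fit_with_ebes({i: rng.normal(0, 0.25) for i in ids})
        cov = pd.DataFrame({"bmi": rng.normal(24, 3, 30)}, index=list(ids))
        res = dg.covariate_screen(fit, cov,
                                  fit_candidate=lambda e, c: (_ for _ in ()).throw(
                                      AssertionError("should not refit")))
        assert res.stepping is not None and res.stepping.empty
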