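import numpy as np
import pytest

from pulsepkpd import nlme, trial_synth as ts


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_gh_trial():
    """Small mixed placebo trial with GH profiles (shared, read-only)."""
    return ts.simulate_trial([("placebo", 0, 4), ("placebo m.a.d.", 0, 2)],
                             seed=11, hormones=("GH",))


@pytest.fixture(scope="session")
def small_prl_trial():
    """Placebo + active PRL trial (shared, read-only)."""
    return ts.simulate_trial([("placebo", 0, 4), ("1.5 mg s.a.d.", 4, 0)],
                             seed=12, hormones=("PRL",))


class LinearModel:
    """y = mu + eta + eps, one observation per subject: the closed-form
    marginal-likelihood oracle used to pin down the FOCE objective."""

    hormone = "LIN"

    def eta_info(self, subject, pset):
        v = pset.omega2.get("mu", 0.0)
        if v > 0:
            return np.array([v]), [("iiv", "mu")]
        return np.array([]), []

    def predict(self, subject, theta, eta, meta):
        shift = eta[0] if len(eta) else 0.0
        return np.full(subject.times.size, theta["mu"] + shift)

    def jacobian(self, subject, theta, eta, meta, f0):
        return np.ones((f0.size, len(eta)))

    def simulate(self, subject, pset, rng):
        var, meta = self.eta_info(subject, pset)
        eta = rng.normal(0, np.sqrt(var)) if var.size else np.empty(0)
        f = self.predict(subject, pset.values(), eta, meta)
        return f + rng.normal(0, np.sqrt(pset.sigma2), f.size)


@pytest.fixture()
def linear_model():
    return LinearModel()


def make_linear_subjects(values, sigma=None):
    return [nlme.SubjectData(id=i + 1, times=[0.0], y=[v], occ=[1])
            for i, v in enumerate(values)]


@pytest.fixture()
def linear_pset():
    return nlme.ParameterSet({"mu": nlme.Theta(2.0, "identity")},
                             omega2={"mu": 0.5}, sigma2=0.3,
                             error_model="additive")
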