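"""Nonlinear mixed-effects estimation for the hormone models.

Population parameters are estimated by minimizing an objective function value
(OFV, -2 log approximate marginal likelihood).  The marginal likelihood over
each subject's random effects is approximated by Laplace's method at the
posterior mode with interaction (the residual variance depends on the
individual prediction), i.e. a first-order-conditional-style objective:

    OFV_i = h(eta_hat) + log det(H/2) - q log(2 pi)
    h(eta) = sum_j [ (y_j - f_j)^2 / v_j + log(2 pi v_j) ]
             + eta' Omega^-1 eta + log det(2 pi Omega)

with ``v = sigma2 * f^2`` (proportional error) or ``sigma2`` (additive), and
``H`` the Gauss-Newton curvature ``2 J' W J + 2 Omega^-1`` at the mode.  For
a linear model with additive error the approximation is exact.

Random effects are log-normal on positive parameters (additive on phase
shifts), with optional between-occasion effects (one independent draw per
sampling day) and, for GH, one amplitude effect per secretion pulse.  The
inner problem is solved by a damped Newton iteration whose Jacobian uses the
analytic linearity of the GH model in the pulse masses.

The outer problem runs Nelder-Mead on transformed parameters (log for
positive, logit-like for the bounded Emax, identity for phases, log for
variances).  Supporting operations: likelihood-ratio testing at the
chi-square threshold, a finite-difference covariance step with relative
standard errors and condition number, and a stratified nonparametric
bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import erfcx, expit, logit

from .structural_models import (
    DrugInput,
    GHParams,
    PRLParams,
    effect_compartment,
    emax_factor,
    gh_pulse_kernel,
    prl_concentration,
    prl_prepare,
)
from .trial_synth import DOSE_CLOCK, DVID_GH, DVID_PRL, LLOQ_GH, Trial

__all__ = [
    "Theta",
    "ParameterSet",
    "SubjectData",
    "FitResult",
    "NestedComparison",
    "GHModel",
    "PRLModel",
    "ofv",
    "fit",
    "lrt",
    "covariance_step",
    "bootstrap",
    "subjects_from_trial",
]

_LOG2PI = math.log(2.0 * math.pi)
_SQRT2 = math.sqrt(2.0)
_SQRTPI = math.sqrt(math.pi)


def _expc(x: float) -> float:
    """exp with the argument clamped to +/-40 (inner line searches may probe
    absurd random-effect values; the clamp keeps the objective finite)."""
    return math.exp(max(min(x, 40.0), -40.0))
PRED_FLOOR = 1e-10
SIGMA2_FLOOR = 1e-6


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------


@dataclass
class Theta:
    value: float
    transform: str = "log"  # 'log' | 'logit_neg' | 'identity'
    fixed: bool = False

    def encode(self) -> float:
        if self.transform == "log":
            return math.log(self.value)
        if self.transform == "logit_neg":  # value in (-1, 0)
            return float(logit(-self.value))
        return self.value

    def decoded(self, x: float) -> float:
        if self.transform == "log":
            return math.exp(x)
        if self.transform == "logit_neg":
            return float(-expit(x))
        return x

    def dvalue_dx(self) -> float:
        """|d value / d encoded| at the current value (delta method)."""
        if self.transform == "log":
            return abs(self.value)
        if self.transform == "logit_neg":
            p = -self.value
            return p * (1.0 - p)
        return 1.0


@dataclass
class ParameterSet:
    """Fixed effects plus variance components of one population model."""

    theta: dict[str, Theta]
    omega2: dict[str, float] = field(default_factory=dict)
    bov2: dict[str, float] = field(default_factory=dict)
    sigma2: float = 0.01
    error_model: str = "proportional"  # 'proportional' | 'additive'
    fixed_omega2: set[str] = field(default_factory=set)
    fixed_bov2: set[str] = field(default_factory=set)
    sigma2_fixed: bool = False

    def __post_init__(self):
        for k, v in {**self.omega2, **self.bov2}.items():
            if v < 0:
                raise ValueError(f"variance {k} must be nonnegative")
        if self.error_model not in ("proportional", "additive"):
            raise ValueError("error_model must be 'proportional' or 'additive'")

    def values(self) -> dict[str, float]:
        return {k: t.value for k, t in self.theta.items()}

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            {k: replace(t) for k, t in self.theta.items()},
            dict(self.omega2), dict(self.bov2), self.sigma2, self.error_model,
            set(self.fixed_omega2), set(self.fixed_bov2), self.sigma2_fixed)

    def with_all_fixed(self, except_names: Sequence[str] = ()) -> "ParameterSet":
        """Freeze every component (the sequential-fit contract: placebo-stage
        estimates and variances are fixed before drug parameters are added),
        then free the named thetas."""
        out = self.copy()
        for name, t in out.theta.items():
            t.fixed = name not in except_names
        out.fixed_omega2 = set(out.omega2)
        out.fixed_bov2 = set(out.bov2)
        out.sigma2_fixed = True
        return out


# --------------------------------------------------------------------------
# data
# --------------------------------------------------------------------------


@dataclass
class SubjectData:
    """One subject's observations of a single hormone.

    ``times`` are hours since (nominal) first dose; ``occ`` labels the
    sampling day (1/2/3 for days 1/7/12).  ``pulses`` maps occasion to pulse
    locations (GH only).  ``clock_offset`` converts to the normalized clock
    (0 = 6 a.m.).
    """

    id: int
    times: np.ndarray
    y: np.ndarray
    occ: np.ndarray
    drug: DrugInput | None = None
    pulses: dict[int, np.ndarray] | None = None
    clock_offset: float = DOSE_CLOCK
    cohort: str = ""
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.occ = np.asarray(self.occ, dtype=int)
        if not (self.times.size == self.y.size == self.occ.size):
            raise ValueError("times, y, occ must have equal length")
        if self.times.size == 0:
            raise ValueError(f"subject {self.id} has no observations")

    @property
    def occasions(self) -> list[int]:
        return sorted(np.unique(self.occ))


def subjects_from_trial(trial: Trial, hormone: str) -> list[SubjectData]:
    """Build estimation-ready subjects from a simulated trial, carrying the
    generator's pulse locations (the deconvolution-informed analogue)."""
    dvid = {"GH": DVID_GH, "PRL": DVID_PRL}[hormone]
    out = []
    for vs in trial.subjects:
        df = trial.events
        rows = df[(df.ID == vs.id) & (df.DVID == dvid) & (df.EVID == 0)]
        if rows.empty:
            continue
        out.append(SubjectData(
            id=vs.id, times=rows.TAD.to_numpy(), y=rows.DV.to_numpy(),
            occ=rows.OCC.to_numpy(), drug=vs.drug,
            pulses={o: np.asarray(t) for o, t in vs.pulse_times.items()} or None,
            cohort=vs.cohort, covariates=dict(vs.covariates)))
    return out


# --------------------------------------------------------------------------
# model adapters
# --------------------------------------------------------------------------


class GHModel:
    """Pulsatile GH model bound to subject data.

    Fixed effects: baseline, width, amplitude, k_el, k_e0, emax, ec50.
    Random effects: IIV on baseline/width/k_el, BOV on width/k_el per
    occasion, and one log-normal amplitude effect per pulse
    (``amplitude_n``).  The drug scales each pulse mass by the inhibitory
    Emax factor of the effect-site concentration at the pulse centre.
    """

    hormone = "GH"
    iiv_effects = ("baseline", "width", "k_el")
    bov_effects = ("width", "k_el")
    pulse_effect = "amplitude_n"
    lloq = LLOQ_GH

    def __init__(self, effect_on: str = "mass"):
        self.effect_on = effect_on

    @staticmethod
    def default_parameters(published: bool = True) -> ParameterSet:
        return ParameterSet(
            theta={
                "baseline": Theta(0.056), "width": Theta(0.184),
                "amplitude": Theta(1.69), "k_el": Theta(3.6),
                "k_e0": Theta(1.25), "emax": Theta(-0.648, "logit_neg"),
                "ec50": Theta(0.609),
            },
            omega2={"baseline": 0.0288, "width": 0.0434, "k_el": 0.225,
                    "amplitude_n": 3.46},
            bov2={"width": 0.104, "k_el": 0.00775},
            sigma2=0.0247,
        )

    # ---- eta bookkeeping -------------------------------------------------

    def eta_info(self, subject: SubjectData, pset: ParameterSet):
        meta: list[tuple] = []
        var: list[float] = []
        for e in self.iiv_effects:
            v = pset.omega2.get(e, 0.0)
            if v > 0:
                meta.append(("iiv", e))
                var.append(v)
        for occ in subject.occasions:
            for e in self.bov_effects:
                v = pset.bov2.get(e, 0.0)
                if v > 0:
                    meta.append(("bov", e, occ))
                    var.append(v)
        v_amp = pset.omega2.get(self.pulse_effect, 0.0)
        if v_amp > 0 and subject.pulses:
            for occ in subject.occasions:
                for j in range(len(subject.pulses.get(occ, ()))):
                    meta.append(("pulse", occ, j))
                    var.append(v_amp)
        return np.asarray(var), meta

    def _pulse_factors(self, subject: SubjectData, occ: int,
                       theta: dict[str, float]) -> np.ndarray:
        pt = np.asarray(subject.pulses.get(occ, np.empty(0))) if subject.pulses \
            else np.empty(0)
        if subject.drug is None or pt.size == 0:
            return np.ones(pt.size)
        # cache the effect-site concentrations on the subject itself so that
        # one model instance can serve many data sets without key collisions
        cache = subject.__dict__.setdefault("_ce_cache", {})
        key = (occ, round(theta["k_e0"], 12))
        ce = cache.get(key)
        if ce is None:
            ce = effect_compartment(subject.drug, theta["k_e0"], pt)
            if len(cache) > 64:
                cache.clear()
            cache[key] = ce
        return emax_factor(ce, theta["emax"], theta["ec50"])

    def _layout(self, subject: SubjectData, meta: list[tuple]):
        """Index arrays mapping the eta vector onto occasions and pulses
        (cached per subject and meta signature)."""
        cache = subject.__dict__.setdefault("_layout_cache", {})
        key = tuple(meta)
        lay = cache.get(key)
        if lay is not None:
            return lay
        idx = {m: i for i, m in enumerate(meta)}
        occ_lay = {}
        for occ in subject.occasions:
            pt = subject.pulses.get(occ, np.empty(0)) if subject.pulses else np.empty(0)
            pulse_idx = np.array([idx.get(("pulse", occ, j), -1)
                                  for j in range(pt.size)], dtype=int)
            occ_lay[occ] = dict(
                sel=np.flatnonzero(subject.occ == occ),
                pt=np.asarray(pt, dtype=float),
                i_b=idx.get(("iiv", "baseline"), -1),
                i_w=idx.get(("iiv", "width"), -1),
                i_k=idx.get(("iiv", "k_el"), -1),
                i_bw=idx.get(("bov", "width", occ), -1),
                i_bk=idx.get(("bov", "k_el", occ), -1),
                pulse_idx=pulse_idx,
            )
        if len(cache) > 16:
            cache.clear()
        cache[key] = occ_lay
        return occ_lay

    @staticmethod
    def _kernel_parts(u, w, k, want_jac):
        """Kernel matrix K(u; w, k) and (optionally) its partial derivatives
        with respect to width and elimination rate, stable in both branches."""
        b = (k * w * w - u) / (w * _SQRT2)
        tail = b < -20.0
        bs = np.where(tail, 0.0, b)
        g = np.exp(-(u * u) / (2.0 * w * w))
        ex = erfcx(bs)
        decay = np.exp(np.minimum(k * (k * w * w / 2.0 - u), 700.0))
        K = np.where(tail, decay, 0.5 * ex * g)
        if not want_jac:
            return K, None, None
        dex = 2.0 * bs * ex - 2.0 / _SQRTPI  # erfcx'
        db_dw = k / _SQRT2 + u / (_SQRT2 * w * w)
        db_dk = w / _SQRT2
        dK_dw = 0.5 * g * (dex * db_dw + ex * u * u / w**3)
        dK_dk = 0.5 * g * dex * db_dk
        dK_dw = np.where(tail, k * k * w * decay, dK_dw)
        dK_dk = np.where(tail, (k * w * w - u) * decay, dK_dk)
        return K, dK_dw, dK_dk

    def _eval(self, subject: SubjectData, theta: dict[str, float],
              eta: np.ndarray, meta: list[tuple], want_jac: bool):
        lay = self._layout(subject, meta)
        f = np.empty(subject.times.size)
        J = np.zeros((f.size, eta.size)) if want_jac else None

        def e(i, extra=-1):
            v = eta[i] if i >= 0 else 0.0
            if extra >= 0:
                v += eta[extra]
            return v

        for occ, L in lay.items():
            sel = L["sel"]
            t = subject.times[sel]
            b = theta["baseline"] * _expc(e(L["i_b"]))
            w = theta["width"] * _expc(e(L["i_w"], L["i_bw"]))
            k = theta["k_el"] * _expc(e(L["i_k"], L["i_bk"]))
            pt = L["pt"]
            if pt.size == 0:
                f[sel] = b
                if want_jac and L["i_b"] >= 0:
                    J[sel, L["i_b"]] = b
                continue
            pidx = L["pulse_idx"]
            amp_eta = np.where(pidx >= 0, eta[np.maximum(pidx, 0)], 0.0)
            factors = self._pulse_factors(subject, occ, theta)
            amps = theta["amplitude"] * np.exp(np.clip(amp_eta, -40, 40)) * factors
            u = t[:, None] - pt[None, :]
            K, dK_dw, dK_dk = self._kernel_parts(u, w, k, want_jac)
            f[sel] = b + K @ amps
            if not want_jac:
                continue
            if L["i_b"] >= 0:
                J[sel, L["i_b"]] = b
            # chain rule: d f / d eta_w = w * d f / d w, etc.
            dw_col = (dK_dw @ amps) * w
            dk_col = (dK_dk @ amps) * k
            for i in (L["i_w"], L["i_bw"]):
                if i >= 0:
                    J[sel, i] += dw_col
            for i in (L["i_k"], L["i_bk"]):
                if i >= 0:
                    J[sel, i] += dk_col
            cols = K * amps[None, :]  # pulse-mass columns (model linear in mass)
            for j, pi in enumerate(pidx):
                if pi >= 0:
                    J[sel, pi] = cols[:, j]
        return f, J

    def predict(self, subject: SubjectData, theta: dict[str, float],
                eta: np.ndarray, meta: list[tuple]) -> np.ndarray:
        return self._eval(subject, theta, eta, meta, False)[0]

    def jacobian(self, subject: SubjectData, theta: dict[str, float],
                 eta: np.ndarray, meta: list[tuple],
                 f0: np.ndarray) -> np.ndarray:
        return self._eval(subject, theta, eta, meta, True)[1]

    def simulate(self, subject: SubjectData, pset: ParameterSet,
                 rng: np.random.Generator) -> np.ndarray:
        var, meta = self.eta_info(subject, pset)
        eta = rng.normal(0.0, np.sqrt(var)) if var.size else np.empty(0)
        f = self.predict(subject, pset.values(), eta, meta)
        y = _add_residual(f, pset, rng)
        return np.maximum(y, self.lloq)


class PRLModel:
    """PRL pool model bound to subject data.

    Fixed effects: k_r, k_el, k_s, amp24, phase24, amp12, phase12, emax,
    ec50, slope; IIV (log-normal) on k_s and the two circadian amplitudes.
    """

    hormone = "PRL"
    iiv_effects = ("k_s", "amp24", "amp12")
    bov_effects = ()
    pulse_effect = None
    lloq = None

    def __init__(self, step: float = 0.1, run_in: float = 24.0):
        self.step = step
        self.run_in = run_in

    @staticmethod
    def default_parameters(published: bool = True) -> ParameterSet:
        return ParameterSet(
            theta={
                "k_r": Theta(0.011), "k_el": Theta(1.25), "k_s": Theta(13.3),
                "amp24": Theta(0.168), "phase24": Theta(17.3, "identity"),
                "amp12": Theta(0.095), "phase12": Theta(10.2, "identity"),
                "emax": Theta(-0.91, "logit_neg"), "ec50": Theta(1.27),
                "slope": Theta(2.73),
            },
            omega2={"k_s": 0.068, "amp24": 0.57, "amp12": 0.87},
            sigma2=0.049,
        )

    def eta_info(self, subject: SubjectData, pset: ParameterSet):
        meta = []
        var = []
        for e in self.iiv_effects:
            v = pset.omega2.get(e, 0.0)
            if v > 0:
                meta.append(("iiv", e))
                var.append(v)
        return np.asarray(var), meta

    def predict(self, subject: SubjectData, theta: dict[str, float],
                eta: np.ndarray, meta: list[tuple]) -> np.ndarray:
        idx = {m: i for i, m in enumerate(meta)}

        def scale(name):
            i = idx.get(("iiv", name))
            return _expc(eta[i]) if i is not None else 1.0

        params = PRLParams(
            k_r=theta["k_r"], k_el=theta["k_el"],
            k_s=theta["k_s"] * scale("k_s"),
            amp24=theta["amp24"] * scale("amp24"), phase24=theta["phase24"],
            amp12=theta["amp12"] * scale("amp12"), phase12=theta["phase12"],
            emax=theta["emax"], ec50=theta["ec50"], slope=theta["slope"],
        )
        # keep the release factor positive for extreme inner-eta excursions
        s = abs(params.amp24) + abs(params.amp12)
        if s >= 0.99:
            shrink = 0.99 / s
            params = replace(params, amp24=params.amp24 * shrink,
                             amp12=params.amp12 * shrink)
        prep_cache = subject.__dict__.setdefault("_prl_prep", {})
        key = (self.step, self.run_in)
        prepared = prep_cache.get(key)
        order = np.argsort(subject.times)
        t_sorted = subject.times[order]
        if prepared is None:
            prepared = prl_prepare(subject.drug, t_sorted[0] - self.run_in,
                                   t_sorted[-1], self.step)
            prep_cache[key] = prepared
        out = np.empty(subject.times.size)
        out[order] = prl_concentration(params, subject.drug, subject.clock_offset,
                                       t_sorted, run_in=self.run_in,
                                       step=self.step, prepared=prepared)
        return out

    def jacobian(self, subject, theta, eta, meta, f0):
        J = np.empty((f0.size, eta.size))
        h = 1e-5
        for i in range(eta.size):
            ep = eta.copy()
            ep[i] += h
            J[:, i] = (self.predict(subject, theta, ep, meta) - f0) / h
        return J

    def simulate(self, subject: SubjectData, pset: ParameterSet,
                 rng: np.random.Generator,
                 amplitude_sum_cap: float = 0.95) -> np.ndarray:
        var, meta = self.eta_info(subject, pset)
        theta = pset.values()
        for _ in range(1000):
            eta = rng.normal(0.0, np.sqrt(var)) if var.size else np.empty(0)
            # the population law for the circadian amplitudes is the
            # truncated log-normal that keeps the release rate positive --
            # the same rule the trial generator applies
            idx = {m: i for i, m in enumerate(meta)}
            s24 = abs(theta["amp24"]) * math.exp(eta[idx[("iiv", "amp24")]]) \
                if ("iiv", "amp24") in idx else abs(theta["amp24"])
            s12 = abs(theta["amp12"]) * math.exp(eta[idx[("iiv", "amp12")]]) \
                if ("iiv", "amp12") in idx else abs(theta["amp12"])
            if s24 + s12 < amplitude_sum_cap:
                break
        f = self.predict(subject, theta, eta, meta)
        return _add_residual(f, pset, rng)


def _add_residual(f: np.ndarray, pset: ParameterSet,
                  rng: np.random.Generator) -> np.ndarray:
    eps = rng.normal(0.0, math.sqrt(max(pset.sigma2, SIGMA2_FLOOR)), f.size)
    if pset.error_model == "proportional":
        return f * (1.0 + eps)
    return f + eps


# --------------------------------------------------------------------------
# objective function
# --------------------------------------------------------------------------


def _residual_m2ll(y, f, pset) -> float:
    """-2 log likelihood of the residuals at fixed individual prediction."""
    s2 = max(pset.sigma2, SIGMA2_FLOOR)
    if pset.error_model == "proportional":
        fm = np.maximum(f, PRED_FLOOR)
        v = s2 * fm * fm
    else:
        v = np.full(f.shape, s2)
    e = y - f
    return float(np.sum(e * e / v + np.log(2.0 * np.pi * v)))


def _inner_h(y, f, eta, var_eta, pset) -> float:
    pen = float(np.sum(eta * eta / var_eta) + np.sum(np.log(2.0 * np.pi * var_eta)))
    return _residual_m2ll(y, f, pset) + pen


def _inner_grad_hess(model, subject, theta, eta, meta, var_eta, pset, f=None):
    if f is None:
        f = model.predict(subject, theta, eta, meta)
    J = model.jacobian(subject, theta, eta, meta, f)
    y = subject.y
    e = y - f
    s2 = max(pset.sigma2, SIGMA2_FLOOR)
    if pset.error_model == "proportional":
        fm = np.maximum(f, PRED_FLOOR)
        v = s2 * fm * fm
        # d/deta of sum(e^2/v + log v) with v = s2 f^2 (interaction)
        coef = -2.0 * e / v - 2.0 * e * e / (s2 * fm**3) + 2.0 / fm
    else:
        v = np.full(f.shape, s2)
        coef = -2.0 * e / v
    grad = J.T @ coef + 2.0 * eta / var_eta
    w = 1.0 / v
    hess = 2.0 * (J.T * w) @ J + 2.0 * np.diag(1.0 / var_eta)
    return f, J, grad, hess


def _solve_inner(model, subject, theta, pset, eta0=None, max_iter=80,
                 gtol=5e-3):
    """Posterior mode of the random effects by damped Newton with
    Gauss-Newton curvature.

    Steps are capped (and iterates boxed) in units of the prior standard
    deviation: a random effect more than ~10 prior SDs from zero has
    essentially no posterior mass, and the cap keeps weakly informed effects
    (e.g. pulses at the edge of the sampling window) from running away along
    nearly flat likelihood directions.  Restarts from zero on failure.
    """
    var_eta, meta = model.eta_info(subject, pset)
    q = var_eta.size
    if q == 0:
        f = model.predict(subject, theta, np.empty(0), meta)
        return np.empty(0), meta, var_eta, f, None

    sd = np.sqrt(var_eta)
    box = 10.0 * sd
    for attempt in range(3):
        eta = (np.zeros(q) if eta0 is None or attempt > 0 or eta0.size != q
               else np.clip(eta0, -box, box))
        if attempt == 2:
            eta = eta + 0.1 * sd
        f = model.predict(subject, theta, eta, meta)
        h_val = _inner_h(subject.y, f, eta, var_eta, pset)
        lam = 0.0
        ok = True
        for _ in range(max_iter):
            f, J, grad, hess = _inner_grad_hess(model, subject, theta, eta,
                                                meta, var_eta, pset, f)
            gnorm = float(np.max(np.abs(grad * sd)))
            if gnorm < gtol:
                break
            try:
                step = np.linalg.solve(hess + lam * np.eye(q), -grad)
            except np.linalg.LinAlgError:
                ok = False
                break
            rel = np.max(np.abs(step) / np.maximum(sd, 1e-12))
            if rel > 3.0:  # trust region: at most 3 prior SDs per move
                step *= 3.0 / rel
            # backtracking line search on h
            alpha = 1.0
            for _ls in range(25):
                cand = np.clip(eta + alpha * step, -box, box)
                f_c = model.predict(subject, theta, cand, meta)
                h_c = _inner_h(subject.y, f_c, cand, var_eta, pset)
                if h_c < h_val - 1e-10:
                    eta, f, h_val = cand, f_c, h_c
                    lam *= 0.3
                    break
                alpha *= 0.5
            else:
                lam = max(lam * 10.0, 1e-4)
                if lam > 1e8:
                    break
        if ok and np.all(np.isfinite(eta)):
            _, J, _, hess = _inner_grad_hess(model, subject, theta, eta, meta,
                                             var_eta, pset, f)
            return eta, meta, var_eta, f, hess
    raise RuntimeError(f"inner optimization failed for subject {subject.id}")


def _subject_ofv(model, subject, theta, pset, eta0=None, gtol=5e-3):
    eta, meta, var_eta, f, hess = _solve_inner(model, subject, theta, pset, eta0,
                                               gtol=gtol)
    if hess is None:
        return _residual_m2ll(subject.y, f, pset), eta, meta
    q = eta.size
    sign, logdet = np.linalg.slogdet(hess / 2.0)
    if sign <= 0:
        # curvature lost positive definiteness; fall back to the prior scale
        logdet = float(np.sum(np.log(1.0 / var_eta)))
    val = _inner_h(subject.y, f, eta, var_eta, pset) + logdet - q * _LOG2PI
    return val, eta, meta


def ofv(model, subjects: Sequence[SubjectData], pset: ParameterSet,
        eta_cache: dict | None = None, gtol: float = 5e-3) -> float:
    """Total objective function value (-2 log approximate marginal
    likelihood, extended-least-squares convention) over all subjects."""
    total = 0.0
    for s in subjects:
        eta0 = eta_cache.get(s.id) if eta_cache is not None else None
        val, eta, _ = _subject_ofv(model, s, pset.values(), pset, eta0, gtol=gtol)
        if eta_cache is not None:
            eta_cache[s.id] = eta
        total += val
    return total


def ebes(model, subjects, pset) -> dict[int, tuple[np.ndarray, list[tuple]]]:
    """Empirical Bayes estimates (posterior modes) per subject."""
    out = {}
    for s in subjects:
        eta, meta, *_ = _solve_inner(model, s, pset.values(), pset, gtol=1e-5)
        out[s.id] = (eta, meta)
    return out


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


@dataclass
class FitResult:
    params: ParameterSet
    ofv: float
    free_names: list[str]
    ebes: dict[int, tuple[np.ndarray, list[tuple]]]
    converged: bool
    n_evals: int
    se: dict[str, float] | None = None
    rse: dict[str, float] | None = None
    cov: np.ndarray | None = None
    condition_number: float | None = None
    cov_status: str = "not run"
    message: str = ""

    @property
    def estimates(self) -> dict[str, float]:
        out = dict(self.params.values())
        out.update({f"omega2_{k}": v for k, v in self.params.omega2.items()})
        out.update({f"bov2_{k}": v for k, v in self.params.bov2.items()})
        out["sigma2"] = self.params.sigma2
        return out


class _Parameterization:
    """Maps the free components of a ParameterSet onto an unconstrained
    vector (thetas via their transforms, variances via log)."""

    def __init__(self, pset: ParameterSet):
        self.template = pset.copy()
        self.entries: list[tuple] = []
        for name, t in pset.theta.items():
            if not t.fixed:
                self.entries.append(("theta", name))
        for name, v in pset.omega2.items():
            if name not in pset.fixed_omega2:
                if v <= 0:
                    raise ValueError(f"free variance omega2[{name}] must start > 0")
                self.entries.append(("omega2", name))
        for name, v in pset.bov2.items():
            if name not in pset.fixed_bov2:
                if v <= 0:
                    raise ValueError(f"free variance bov2[{name}] must start > 0")
                self.entries.append(("bov2", name))
        if not pset.sigma2_fixed:
            self.entries.append(("sigma2", None))

    @property
    def names(self) -> list[str]:
        return [k if g == "sigma2" else (k if g == "theta" else f"{g}_{k}")
                for g, k in self.entries]

    def encode(self, pset: ParameterSet) -> np.ndarray:
        x = []
        for g, k in self.entries:
            if g == "theta":
                x.append(pset.theta[k].encode())
            elif g == "omega2":
                x.append(math.log(pset.omega2[k]))
            elif g == "bov2":
                x.append(math.log(pset.bov2[k]))
            else:
                x.append(math.log(pset.sigma2))
        return np.asarray(x)

    def decode(self, x: np.ndarray) -> ParameterSet:
        p = self.template.copy()
        for xi, (g, k) in zip(x, self.entries):
            if g == "theta":
                p.theta[k].value = p.theta[k].decoded(float(xi))
            elif g == "omega2":
                p.omega2[k] = math.exp(min(xi, 50.0))
            elif g == "bov2":
                p.bov2[k] = math.exp(min(xi, 50.0))
            else:
                p.sigma2 = math.exp(min(xi, 50.0))
        return p


def fit(model, subjects: Sequence[SubjectData], start: ParameterSet,
        maxfev: int = 4000, fatol: float = 5e-3, xatol: float = 5e-4,
        init_step: float = 0.15, verbose: bool = False) -> FitResult:
    """Minimize the OFV over the free (transformed) parameters.

    The inner random-effect modes are warm-started across outer evaluations.
    The sequential protocol is expressed through the fixed-flags of
    ``start`` (see :meth:`ParameterSet.with_all_fixed`).
    """
    par = _Parameterization(start)
    x0 = par.encode(start)
    eta_cache: dict[int, np.ndarray] = {}
    n_eval = [0]

    def objective(x):
        n_eval[0] += 1
        p = par.decode(x)
        try:
            val = ofv(model, subjects, p, eta_cache)
        except (RuntimeError, FloatingPointError, np.linalg.LinAlgError):
            return 1e12
        if not np.isfinite(val):
            return 1e12
        if verbose and n_eval[0] % 50 == 0:
            print(f"  eval {n_eval[0]}: OFV {val:.3f}")
        return val

    if x0.size == 0:
        val = ofv(model, subjects, start)
        return FitResult(start.copy(), val, [], ebes(model, subjects, start),
                         True, 1)

    # explicit initial simplex: a fixed step on the transformed (log/logit)
    # scale; the scipy default perturbs near-zero coordinates by only
    # ~2.5e-4, which collapses below fatol and stalls the search
    simplex = np.vstack([x0] + [x0 + init_step * e
                                for e in np.eye(x0.size)])
    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options=dict(maxfev=maxfev, fatol=fatol,
                                         xatol=xatol, adaptive=True,
                                         initial_simplex=simplex))
    p_hat = par.decode(res.x)
    final = ofv(model, subjects, p_hat, eta_cache)
    eb = {sid: (eta, _solve_inner(model, s, p_hat.values(), p_hat, eta)[1])
          for s, sid, eta in ((s, s.id, eta_cache[s.id]) for s in subjects)}
    return FitResult(p_hat, final, par.names, eb, bool(res.success),
                     n_eval[0], message=res.message)


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------


@dataclass
class NestedComparison:
    ofv_reduced: float
    ofv_full: float
    df: int
    alpha: float
    critical_value: float
    delta_ofv: float
    significant: bool
    warning: str = ""


def lrt(reduced: FitResult | float, full: FitResult | float, df: int,
        alpha: float = 0.01) -> NestedComparison:
    """Likelihood-ratio test between nested fits.

    At ``alpha = 0.01`` and one added degree of freedom the critical drop is
    the 6.64-point chi-square threshold used throughout model development.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    ofv_r = reduced.ofv if isinstance(reduced, FitResult) else float(reduced)
    ofv_f = full.ofv if isinstance(full, FitResult) else float(full)
    crit = float(stats.chi2.ppf(1.0 - alpha, df))
    delta = ofv_r - ofv_f
    warning = ""
    if delta < 0:
        warning = ("full model has higher OFV than the reduced model; "
                   "likely an optimizer artifact")
    return NestedComparison(ofv_r, ofv_f, df, alpha, crit, delta,
                            bool(delta >= crit), warning)


def _fd_hessian(fun: Callable[[np.ndarray], float], x0: np.ndarray,
                rel_step: float = 1e-4, richardson: bool = True) -> np.ndarray:
    def hess_at(step_scale):
        h = rel_step * step_scale * np.maximum(np.abs(x0), 1.0)
        n = x0.size
        H = np.empty((n, n))
        f0 = fun(x0)
        fp = np.empty(n)
        fm = np.empty(n)
        for i in range(n):
            e = np.zeros(n)
            e[i] = h[i]
            fp[i] = fun(x0 + e)
            fm[i] = fun(x0 - e)
            H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
        for i in range(n):
            for j in range(i + 1, n):
                ei = np.zeros(n); ei[i] = h[i]
                ej = np.zeros(n); ej[j] = h[j]
                fpp = fun(x0 + ei + ej)
                fmm = fun(x0 - ei - ej)
                H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2.0 * f0
                                     - fm[i] - fm[j] + fmm) / (2.0 * h[i] * h[j])
        return H

    H1 = hess_at(1.0)
    if not richardson:
        return H1
    H2 = hess_at(0.5)
    return (4.0 * H2 - H1) / 3.0


def covariance_step(model, subjects, fit_result: FitResult,
                    rel_step: float = 1e-4, richardson: bool = True
                    ) -> FitResult:
    """Standard errors, RSE% and condition number from the finite-difference
    Hessian of the OFV at the optimum (delta method back to natural scale).

    A non-positive-definite Hessian marks the step "failed", mirroring the
    practice of reporting bootstrap intervals instead in that case.
    """
    pset = fit_result.params
    par = _Parameterization(pset)
    x0 = par.encode(pset)
    if x0.size == 0:
        return replace(fit_result, cov_status="failed: no free parameters")
    eta_cache: dict[int, np.ndarray] = {}

    def fun(x):
        # the inner modes must be re-optimized tightly at every probe point:
        # a stale posterior mode biases the finite-difference curvature
        return ofv(model, subjects, par.decode(x), eta_cache, gtol=1e-8)

    H = _fd_hessian(fun, x0, rel_step, richardson)
    try:
        eigvals = np.linalg.eigvalsh(H)
        if np.min(eigvals) <= 0:
            raise np.linalg.LinAlgError("Hessian not positive definite")
        cov_x = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        return replace(fit_result, cov_status=f"failed: {exc}")

    # delta method: d(natural)/d(encoded) for each entry
    deriv = []
    for g, k in par.entries:
        if g == "theta":
            deriv.append(pset.theta[k].dvalue_dx())
        elif g == "omega2":
            deriv.append(pset.omega2[k])
        elif g == "bov2":
            deriv.append(pset.bov2[k])
        else:
            deriv.append(pset.sigma2)
    deriv = np.asarray(deriv)
    cov_nat = cov_x * np.outer(deriv, deriv)
    se_nat = np.sqrt(np.maximum(np.diag(cov_nat), 0.0))
    values = []
    for g, k in par.entries:
        if g == "theta":
            values.append(pset.theta[k].value)
        elif g == "omega2":
            values.append(pset.omega2[k])
        elif g == "bov2":
            values.append(pset.bov2[k])
        else:
            values.append(pset.sigma2)
    values = np.asarray(values)
    rse = 100.0 * se_nat / np.maximum(np.abs(values), 1e-300)
    d = np.sqrt(np.diag(cov_nat))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov_nat / np.outer(d, d)
    ceig = np.linalg.eigvalsh(corr)
    cond = float(np.max(ceig) / max(np.min(ceig), 1e-300))
    names = par.names
    return replace(fit_result,
                   se=dict(zip(names, se_nat)), rse=dict(zip(names, rse)),
                   cov=cov_nat, condition_number=cond, cov_status="ok")


@dataclass
class BootstrapResult:
    medians: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    minimization_success: float
    covariance_success: float | None
    replicates: "object"  # pandas DataFrame of per-replicate estimates


def bootstrap(model, subjects: Sequence[SubjectData], fit_result: FitResult,
              n_samples: int, seed: int = 0, stratify: bool = True,
              identity_first: bool = False, maxfev: int = 1500,
              run_covariance: bool = False) -> BootstrapResult:
    """Nonparametric bootstrap: resample subjects with replacement (stratified
    by cohort), refit, and report per-parameter medians and 95% percentile
    intervals plus success rates."""
    import pandas as pd

    if n_samples < 1:
        raise ValueError("need n_samples >= 1")
    rng = np.random.default_rng(seed)
    strata: dict[str, list[SubjectData]] = {}
    for s in subjects:
        strata.setdefault(s.cohort if stratify else "all", []).append(s)

    rows = []
    n_min_ok = 0
    n_cov_ok = 0
    for rep in range(n_samples):
        if identity_first and rep == 0:
            sample = list(subjects)
        else:
            sample = []
            for group in strata.values():
                picks = rng.integers(0, len(group), len(group))
                sample.extend(group[i] for i in picks)
            sample = [replace(s, id=i + 1) for i, s in enumerate(sample)]
        try:
            r = fit(model, sample, fit_result.params, maxfev=maxfev)
        except RuntimeError:
            rows.append({})
            continue
        if not np.isfinite(r.ofv):
            rows.append({})
            continue
        n_min_ok += 1
        if run_covariance:
            r = covariance_step(model, sample, r, richardson=False)
            if r.cov_status == "ok":
                n_cov_ok += 1
        rows.append(r.estimates)
    if n_min_ok == 0:
        raise RuntimeError("all bootstrap replicates failed to minimize")
    df = pd.DataFrame(rows)
    med = df.median(numeric_only=True).to_dict()
    lo = df.quantile(0.025, numeric_only=True).to_dict()
    hi = df.quantile(0.975, numeric_only=True).to_dict()
    return BootstrapResult(med, lo, hi, n_min_ok / n_samples,
                           (n_cov_ok / n_samples) if run_covariance else None,
                           df)
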