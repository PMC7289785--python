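"""Deterministic forward models for pulsatile GH and circadian PRL secretion.

Growth hormone (GH) is secreted in discrete Gaussian-shaped pulses on top of a
constant basal secretion and eliminated first order from plasma.  A drug acting
through an effect compartment scales the mass of each pulse through an
inhibitory Emax relationship.  Because the plasma equation is linear, the
response to a unit-mass Gaussian secretion event has a closed form (a Gaussian
convolved with an exponential); the default GH evaluation path uses that
superposition and an ODE route is provided for cross-checking.

Prolactin (PRL) follows a pool (precursor) model: synthesis at rate ``k_s``
into a pool, release into plasma at rate ``k_r`` modulated by two circadian
cosines (24 h and 12 h periods) and directly inhibited by plasma drug
concentration via Emax; cumulative drug exposure additionally depresses the
synthesis rate through a saturating slope term.  Given a tabulated drug
concentration the system is linear with time-varying coefficients, and is
integrated with an exponential scheme that is exact for piecewise-linear
inputs on the evaluation grid.

Units: time h, hormone concentration ng/mL, drug concentration µg/L,
cumulative exposure mg·h/L, dose mg.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import lfilter
from scipy.special import erfcx

__all__ = [
    "GHParams",
    "PRLParams",
    "DrugInput",
    "circadian_factor",
    "exposure_inhibition",
    "emax_factor",
    "effect_compartment",
    "cumulative_exposure",
    "gh_pulse_kernel",
    "gh_concentration",
    "prl_concentration",
    "prl_prepare",
]

_SQRT2 = np.sqrt(2.0)
_SQRT2PI = np.sqrt(2.0 * np.pi)

#: floor applied to the circadian release factor so that an extreme
#: random-effect draw can never produce a negative release rate
CIRCADIAN_FLOOR = 1e-6


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------


@dataclass
class GHParams:
    """Structural parameters of the pulsatile GH model.

    ``baseline`` is the steady-state baseline concentration (ng/mL); the basal
    secretion rate is ``baseline * k_el``.  ``amplitude`` is the typical pulse
    mass, i.e. the time-integrated secretion of one pulse per unit volume
    (ng/mL); the Gaussian secretion-rate bump of width ``width`` (SD, h) with
    that mass has height ``mass / (width * sqrt(2*pi))``.
    """

    baseline: float = 0.056
    width: float = 0.184
    amplitude: float = 1.69
    k_el: float = 3.6
    k_e0: float = 1.25
    emax: float = -0.648
    ec50: float = 0.609
    gamma: float = 1.0

    def validated(self) -> "GHParams":
        if min(self.baseline, self.width, self.amplitude, self.k_el,
               self.k_e0, self.ec50) <= 0:
            raise ValueError("GH rates, width, amplitude and EC50 must be > 0")
        if not -1.0 <= self.emax <= 0.0:
            raise ValueError("GH Emax must lie in [-1, 0]")
        if self.gamma < 1.0:
            raise ValueError("Hill coefficient must be >= 1")
        return self


@dataclass
class PRLParams:
    """Structural parameters of the PRL pool model (Table-style defaults)."""

    k_r: float = 0.011
    k_el: float = 1.25
    k_s: float = 13.3
    amp24: float = 0.168
    phase24: float = 17.3
    amp12: float = 0.095
    phase12: float = 10.2
    emax: float = -0.91
    ec50: float = 1.27
    slope: float = 2.73

    def validated(self) -> "PRLParams":
        if min(self.k_r, self.k_el, self.k_s, self.ec50) <= 0:
            raise ValueError("PRL rate constants and EC50 must be > 0")
        if abs(self.amp24) + abs(self.amp12) >= 1.0:
            raise ValueError(
                "circadian amplitude sum must stay below 1 so that the "
                "release rate remains positive"
            )
        if not -1.0 <= self.emax <= 0.0:
            raise ValueError("PRL Emax must lie in [-1, 0]")
        return self


@dataclass
class DrugInput:
    """Tabulated plasma drug concentration with linear interpolation.

    ``first_dose_time`` anchors the cumulative-exposure integral; outside the
    tabulated range the concentration is held at the edge values (zero before
    the first dose in every profile the simulator produces).
    """

    times: np.ndarray
    conc: np.ndarray
    first_dose_time: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.conc.shape:
            raise ValueError("times and conc must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("drug input times must be strictly increasing")
        if np.any(self.conc < -1e-12):
            raise ValueError("drug concentrations must be nonnegative")
        self.conc = np.maximum(self.conc, 0.0)
        if self.first_dose_time is None:
            self.first_dose_time = float(self.times[0])

    def __call__(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.times, self.conc)

    @classmethod
    def zero(cls, t0: float = 0.0, t1: float = 1.0) -> "DrugInput":
        return cls(np.array([t0, t1]), np.zeros(2))


# --------------------------------------------------------------------------
# elementary pharmacodynamic building blocks
# --------------------------------------------------------------------------


def circadian_factor(t, amplitude: float, phase: float, period: float = 24.0):
    """Diurnal deviation ``amplitude * cos(2*pi*(t - phase)/period)``.

    ``t`` is clock time in hours (0 = 6 a.m. in the normalized convention);
    the returned value oscillates about zero (the mesor contributes the 1 in
    ``k_r * (1 + DIU24 + DIU12)``).
    """
    if period <= 0:
        raise ValueError("period must be positive")
    t = np.asarray(t, dtype=float)
    return amplitude * np.cos(2.0 * np.pi * (t - phase) / period)


def exposure_inhibition(cum_exposure, slope: float):
    """Saturating fraction ``x*s / (1 + x*s)`` of synthesis-rate inhibition.

    ``cum_exposure`` is cumulative drug exposure in mg·h/L.  Returns a value
    in [0, 1): zero at zero exposure, approaching full inhibition as the
    product grows.  A nonpositive slope disables the mechanism.
    """
    x = np.asarray(cum_exposure, dtype=float)
    if np.any(x < 0):
        raise ValueError("cumulative exposure must be nonnegative")
    xs = x * slope
    xs = np.maximum(xs, 0.0)  # guard: negative slope means no inhibition
    return xs / (1.0 + xs)


def emax_factor(conc, emax: float, ec50: float, gamma: float = 1.0):
    """Multiplicative inhibition factor ``1 + Emax*C^g/(EC50^g + C^g)``.

    With Emax in [-1, 0] the factor lies in (0, 1]; it equals 1 at zero
    concentration and ``1 + Emax`` at saturating concentration.
    """
    c = np.maximum(np.asarray(conc, dtype=float), 0.0)
    if gamma == 1.0:
        frac = c / (ec50 + c)
    else:
        cg = c**gamma
        frac = cg / (ec50**gamma + cg)
    return 1.0 + emax * frac


# --------------------------------------------------------------------------
# linear first-order responses to tabulated inputs
# --------------------------------------------------------------------------


def _exp_step_coeffs(k: float, h: float) -> tuple[float, float, float]:
    """Exact update coefficients for ``dx/dt = r(t) - k x`` with ``r``
    linear on a step of width ``h``:  x+ = alpha*x + g0*r0 + g1*(r1 - r0)."""
    kh = k * h
    alpha = np.exp(-kh)
    if kh < 1e-8:  # series to avoid catastrophic cancellation
        g0 = h * (1 - kh / 2)
        g1 = h / 2 * (1 - kh / 3)
    else:
        g0 = (1.0 - alpha) / k
        g1 = (h - g0) / kh * 1.0
    return alpha, g0, g1


def _first_order_response(t: np.ndarray, r: np.ndarray, k: float,
                          x0: float = 0.0) -> np.ndarray:
    """Solve ``dx/dt = r(t) - k x`` on the uniform grid ``t`` (piecewise-
    linear ``r``), exactly, via a constant-coefficient IIR recursion."""
    h = t[1] - t[0]
    alpha, g0, g1 = _exp_step_coeffs(k, h)
    beta = (g0 - g1) * r[:-1] + g1 * r[1:]
    # x_{i+1} = alpha * x_i + beta_i  ->  IIR filter with initial state x0
    x = np.empty_like(t)
    x[0] = x0
    zi = np.array([alpha * x0])
    x[1:] = lfilter([1.0], [1.0, -alpha], beta, zi=zi)[0]
    return x


def effect_compartment(drug: DrugInput, k_e0: float, times,
                       grid_step: float = 0.05) -> np.ndarray:
    """Effect-site concentration ``dCe/dt = k_e0 (Cp(t) - Ce)``, Ce(t0)=0.

    Evaluated on an internal uniform grid spanning the drug record and the
    requested times, then interpolated linearly at ``times``.
    """
    if k_e0 <= 0:
        raise ValueError("k_e0 must be positive")
    times = np.asarray(times, dtype=float)
    t0 = min(drug.times[0], times.min()) if times.size else drug.times[0]
    t1 = max(drug.times[-1], times.max()) if times.size else drug.times[-1]
    n = max(int(np.ceil((t1 - t0) / grid_step)), 2)
    grid = np.linspace(t0, t1, n + 1)
    cp = drug(grid)
    ce = _first_order_response(grid, k_e0 * cp, k_e0, x0=0.0)
    return np.interp(times, grid, ce)


def cumulative_exposure(drug: DrugInput, t) -> np.ndarray:
    """Cumulative plasma exposure (mg·h/L) from the first dose to ``t``.

    Trapezoidal integral of the tabulated µg/L concentration, converted to
    mg/L; zero before the first dose and nondecreasing afterwards.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    start = drug.first_dose_time
    grid = drug.times
    seg = np.diff(grid) * (drug.conc[:-1] + drug.conc[1:]) / 2.0
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    base = np.interp(start, grid, cum)
    out = np.interp(t_arr, grid, cum) - base
    # query points beyond the table: hold the last concentration
    beyond = t_arr > grid[-1]
    if np.any(beyond):
        out[beyond] = cum[-1] - base + drug.conc[-1] * (t_arr[beyond] - grid[-1])
    out = np.maximum(out, 0.0) * 1e-3
    return out if np.ndim(t) else float(out[0])


# --------------------------------------------------------------------------
# growth hormone
# --------------------------------------------------------------------------


def gh_pulse_kernel(u, width: float, k_el: float) -> np.ndarray:
    """Plasma response at time lag ``u`` to a unit-mass Gaussian secretion
    event of SD ``width`` centred at lag 0, eliminated at rate ``k_el``.

    Closed form ``0.5 * erfcx((k w^2 - u)/(w sqrt 2)) * exp(-u^2/(2 w^2))``,
    numerically stable for all lags (erfcx is the scaled complementary error
    function).  Integrates to ``1/k_el``, so ``k_el * integral = mass``.
    """
    u = np.asarray(u, dtype=float)
    b = (k_el * width**2 - u) / (width * _SQRT2)
    # erfcx(b) overflows for b << 0 (tail long after the pulse); there
    # erfc(b) -> 2 and the kernel reduces to the pure exponential decay
    # exp(k^2 w^2/2 - k u).
    tail = b < -20.0
    safe = 0.5 * erfcx(np.where(tail, 0.0, b)) * np.exp(-(u**2) / (2.0 * width**2))
    decay = np.exp(np.minimum(k_el * (k_el * width**2 / 2.0 - u), 700.0))
    return np.where(tail, decay, safe)


def _pulse_drug_factors(params: GHParams, pulse_times: np.ndarray,
                        drug: DrugInput | None) -> np.ndarray:
    if drug is None:
        return np.ones(pulse_times.size)
    ce = effect_compartment(drug, params.k_e0, pulse_times)
    return emax_factor(ce, params.emax, params.ec50, params.gamma)


def gh_concentration(params: GHParams, pulse_times, pulse_masses=None,
                     drug: DrugInput | None = None, times=None,
                     method: str = "analytic", effect_on: str = "mass",
                     rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    """GH plasma concentration over ``times``.

    Secretion rate ``S(t) = baseline*k_el + sum_j m_j * F_j * phi(t; T_j, w)``
    with ``phi`` the unit-mass Gaussian density and ``F_j`` the inhibitory
    Emax factor evaluated at the effect-site concentration at the pulse
    centre (``effect_on='mass'``, the default: a pulse is a single secretion
    decision).  ``effect_on='rate'`` instead scales the instantaneous
    secretion rate pointwise and requires the ODE route.  Plasma obeys
    ``dC/dt = S(t) - k_el C`` started at the basal steady state.

    ``method='analytic'`` evaluates the exact superposition of
    Gaussian-convolved-exponential kernels; ``method='ode'`` integrates the
    same system with an adaptive stiff-capable solver (cross-check route).
    """
    params.validated()
    times = np.asarray(times, dtype=float)
    pulse_times = np.asarray(pulse_times, dtype=float)
    if pulse_masses is None:
        pulse_masses = np.full(pulse_times.shape, params.amplitude)
    pulse_masses = np.asarray(pulse_masses, dtype=float)
    if effect_on not in ("mass", "rate"):
        raise ValueError("effect_on must be 'mass' or 'rate'")
    if effect_on == "rate" and method != "ode":
        method = "ode"

    if effect_on == "mass":
        eff_masses = pulse_masses * _pulse_drug_factors(params, pulse_times, drug)
    else:
        eff_masses = pulse_masses

    if method == "analytic":
        c = np.full(times.shape, params.baseline, dtype=float)
        for tj, mj in zip(pulse_times, eff_masses):
            c += mj * gh_pulse_kernel(times - tj, params.width, params.k_el)
        return c

    if method != "ode":
        raise ValueError("method must be 'analytic' or 'ode'")

    w = params.width
    if effect_on == "rate" and drug is not None:
        t_lo = min(times.min(), pulse_times.min() - 6 * w) if pulse_times.size else times.min()
        ce_grid = np.arange(t_lo, times.max() + 0.25, 0.05)
        ce_vals = effect_compartment(drug, params.k_e0, ce_grid)

        def rate_factor(t):
            ce = np.interp(t, ce_grid, ce_vals)
            return emax_factor(ce, params.emax, params.ec50, params.gamma)
    else:
        def rate_factor(t):  # noqa: ANN001 - scalar time
            return 1.0

    basal_rate = params.baseline * params.k_el

    def rhs(t, y):
        s = basal_rate
        if pulse_times.size:
            z = (t - pulse_times) / w
            s = s + float(np.sum(eff_masses * np.exp(-0.5 * z * z))) \
                / (w * _SQRT2PI) * rate_factor(t)
        return [s - params.k_el * y[0]]

    t0 = min(times.min(), pulse_times.min() - 6 * w) if pulse_times.size else times.min()
    sol = solve_ivp(rhs, (t0, times.max()), [params.baseline], t_eval=times,
                    method="LSODA", rtol=rtol, atol=atol, max_step=w / 4)
    if not sol.success:
        raise RuntimeError(f"GH ODE integration failed: {sol.message}")
    return sol.y[0]


# --------------------------------------------------------------------------
# prolactin
# --------------------------------------------------------------------------


def _prl_release_rate(params: PRLParams, clock: np.ndarray,
                      cp: np.ndarray) -> np.ndarray:
    diu = (circadian_factor(clock, params.amp24, params.phase24, 24.0)
           + circadian_factor(clock, params.amp12, params.phase12, 12.0))
    circ = np.maximum(1.0 + diu, CIRCADIAN_FLOOR)
    return params.k_r * circ * emax_factor(cp, params.emax, params.ec50)


def prl_prepare(drug: DrugInput | None, t_start: float, t_end: float,
                step: float = 0.05):
    """Precompute the parameter-independent pieces of a PRL simulation on a
    uniform grid: (grid, plasma drug concentration, cumulative exposure).
    Useful when many parameter vectors are evaluated against one subject."""
    if drug is not None:
        t_start = min(t_start, drug.first_dose_time - 1e-9)
    n = max(int(np.ceil((t_end - t_start) / step)), 4)
    grid = np.linspace(t_start, t_end, n + 1)
    if drug is not None:
        cp = drug(grid)
        cp[grid < drug.first_dose_time] = 0.0
        exposure = cumulative_exposure(drug, grid)
    else:
        cp = np.zeros_like(grid)
        exposure = np.zeros_like(grid)
    return grid, cp, exposure


def prl_concentration(params: PRLParams, drug: DrugInput | None, clock_offset: float,
                      times, run_in: float = 24.0, step: float = 0.05,
                      return_pool: bool = False, prepared=None):
    """PRL plasma concentration over ``times`` (h, trial clock).

    Pool: ``dP/dt = k_s (1 - I(t)) - k_r_eff(t) P``; plasma:
    ``dC/dt = k_r_eff(t) P - k_el C`` with
    ``k_r_eff = k_r (1 + DIU24 + DIU12) * emax_factor(Cp)`` and ``I(t)`` the
    saturating function of cumulative plasma exposure since the first dose.
    Clock time entering the cosines is ``t + clock_offset`` (0 = 6 a.m.).
    A run-in of ``run_in`` hours before the first output, started from the
    mesor steady state (P = k_s/k_r, C = k_s/k_el), settles the circadian
    phase of the fast plasma compartment.

    The time-varying system is linear given the drug input; it is integrated
    on a uniform grid with an integrating-factor scheme for the pool and an
    exact exponential recursion for plasma (both exact for piecewise-linear
    inputs on the grid).
    """
    params.validated()
    times = np.asarray(times, dtype=float)
    if prepared is None:
        prepared = prl_prepare(drug, times.min() - run_in, times.max(), step)
    grid, cp, exposure = prepared
    h = grid[1] - grid[0]
    inh = exposure_inhibition(exposure, params.slope)

    kr_eff = _prl_release_rate(params, grid + clock_offset, cp)
    synth = params.k_s * (1.0 - inh)

    # pool via integrating factor (exponent stays O(k_r * horizon), small)
    a_cum = np.concatenate([[0.0], np.cumsum((kr_eff[:-1] + kr_eff[1:]) * h / 2.0)])
    p0 = params.k_s / params.k_r
    integrand = np.exp(a_cum) * synth
    integral = np.concatenate([[0.0], np.cumsum((integrand[:-1] + integrand[1:]) * h / 2.0)])
    pool = np.exp(-a_cum) * (p0 + integral)

    release = kr_eff * pool
    c0 = params.k_s / params.k_el
    conc = _first_order_response(grid, release, params.k_el, x0=c0)

    out = np.interp(times, grid, conc)
    if return_pool:
        return out, np.interp(times, grid, pool)
    return out


def prl_concentration_ode(params: PRLParams, drug: DrugInput | None,
                          clock_offset: float, times, run_in: float = 24.0,
                          rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    """Adaptive-solver route for the PRL system (cross-check for the default
    exponential-integrator path)."""
    params.validated()
    times = np.asarray(times, dtype=float)
    t_start = times.min() - run_in
    if drug is not None:
        t_start = min(t_start, drug.first_dose_time - 1e-9)

    def rhs(t, y):
        p, c = y
        if drug is not None:
            cpv = float(drug(t)) if t >= drug.first_dose_time else 0.0
            inh = float(exposure_inhibition(cumulative_exposure(drug, t), params.slope)) \
                if t >= drug.first_dose_time else 0.0
        else:
            cpv, inh = 0.0, 0.0
        kr_eff = float(_prl_release_rate(params, np.array([t + clock_offset]),
                                         np.array([cpv]))[0])
        dp = params.k_s * (1.0 - inh) - kr_eff * p
        dc = kr_eff * p - params.k_el * c
        return [dp, dc]

    y0 = [params.k_s / params.k_r, params.k_s / params.k_el]
    sol = solve_ivp(rhs, (t_start, times.max()), y0, t_eval=times,
                    method="LSODA", rtol=rtol, atol=atol, max_step=0.25)
    if not sol.success:
        raise RuntimeError(f"PRL ODE integration failed: {sol.message}")
    return sol.y[1]
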