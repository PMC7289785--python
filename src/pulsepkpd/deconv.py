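"""Deconvolution of pulsatile hormone profiles.

A single profile is decomposed into a constant basal (steady-state baseline)
concentration, a first-order elimination rate, and a set of Gaussian
secretion events, by fitting the convolution model

    C(t) = B + sum_j m_j * K(t - T_j; w, k_el)

where ``K`` is the unit-mass Gaussian-convolved-exponential kernel shared
with the structural GH model.  Events are found by an insert-test-remove
procedure: a candidate event is placed at the peak of the smoothed positive
weighted residual, the whole model is refit, and the candidate is kept only
if it is statistically significant — a one-sided t-test of its mass against
the asymptotic standard error, backed by a partial F-test on the weighted
sum-of-squares drop for the collinear cases where the mass SE degenerates;
events that lose significance are removed.

Long inter-pulse gaps (> 300 min by default) get one additional event at the
gap midpoint (applied once per original gap, to placebo and treated profiles
alike); these augmented events carry a location only and are flagged so that
downstream estimation can treat them as potentially fully inhibited pulses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as _sm_api
from scipy import stats
from scipy.optimize import least_squares
from scipy.special import erfcx

from .structural_models import gh_pulse_kernel

__all__ = [
    "UniformSeries",
    "SecretionEvent",
    "DeconvolutionFit",
    "GridError",
    "regularize_grid",
    "deconvolve",
    "augment_gaps",
    "pulse_frequency_test",
    "interval_summary",
]


class GridError(ValueError):
    """Observation times cannot be arranged on a uniform grid."""


@dataclass(frozen=True)
class UniformSeries:
    """Regularly spaced concentration series (default 20-min grid)."""

    start: float
    interval: float
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.interval <= 0:
            raise ValueError("interval must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.start + self.interval * np.arange(self.values.size)


@dataclass
class SecretionEvent:
    """A Gaussian secretion event: ``mass`` is the time-integral of the
    secretion-rate bump (ng/mL), ``width`` its SD (h).  Augmented events
    (inserted by the gap rule) carry a location only; their mass is NaN and
    is meant to be estimated downstream."""

    location: float
    mass: float
    width: float
    augmented: bool = False

    def __post_init__(self):
        if not self.augmented:
            if not (self.mass > 0):
                raise ValueError("event mass must be positive")
        if not (self.width > 0) and not (self.augmented and math.isnan(self.width)):
            raise ValueError("event width must be positive")


@dataclass
class DeconvolutionFit:
    basal_rate: float            # ng/mL/h, = baseline concentration * k_el
    elimination_rate: float      # /h
    events: list[SecretionEvent]
    series: UniformSeries
    fitted: np.ndarray
    residual_variance: float
    converged: bool = True
    baseline: float = 0.0        # ng/mL

    @property
    def original_events(self) -> list[SecretionEvent]:
        return [e for e in self.events if not e.augmented]


# --------------------------------------------------------------------------
# grid regularization
# --------------------------------------------------------------------------


def regularize_grid(times, values, dose_time: float | None = None,
                    interval: float = 1.0 / 3.0,
                    shift_map: dict[float, float] | None = None,
                    tol: float = 1e-6) -> UniformSeries:
    """Relabel the documented off-grid post-dose samples onto the 20-min grid.

    The 15- and 30-min post-dose points are shifted to 20 and 40 min (values
    untouched); every other time must already sit on the grid.  A residual
    non-uniformity or a duplicate after shifting raises :class:`GridError`
    naming the offending time.
    """
    times = np.asarray(times, dtype=float).copy()
    values = np.asarray(values, dtype=float)
    if times.size != values.size:
        raise ValueError("times and values must have equal length")
    if times.size == 0:
        raise GridError("empty series")
    if np.any(np.diff(times) <= 0):
        raise GridError("times must be strictly increasing")
    if shift_map is None:
        shift_map = {0.25: 1.0 / 3.0, 0.5: 2.0 / 3.0}
    if dose_time is not None:
        for src, dst in shift_map.items():
            hit = np.isclose(times - dose_time, src, atol=tol)
            times[hit] = dose_time + dst
    order = np.argsort(times)
    times, values = times[order], values[order]
    steps = np.diff(times)
    if np.any(steps < tol):
        bad = times[1:][steps < tol][0]
        raise GridError(f"duplicate timestamp at t = {bad:g} h after relabeling")
    k = (times - times[0]) / interval
    off = np.abs(k - np.round(k)) > 1e-4
    if np.any(off):
        raise GridError(f"time {times[off][0]:g} h is not on the {interval:g} h grid")
    idx = np.round(k).astype(int)
    if idx[-1] + 1 != times.size or np.any(np.diff(idx) != 1):
        missing = times[0] + interval * (np.setdiff1d(np.arange(idx[-1] + 1), idx)[0])
        raise GridError(f"missing grid point near t = {missing:g} h")
    return UniformSeries(times[0], interval, values)


# --------------------------------------------------------------------------
# core deconvolution
# --------------------------------------------------------------------------


def _model(t, baseline, k_el, width, masses, locs):
    c = np.full(t.shape, baseline)
    for m, loc in zip(masses, locs):
        c = c + m * gh_pulse_kernel(t - loc, width, k_el)
    return c


def _pack(baseline, k_el, width, masses, locs):
    return np.concatenate([[baseline, k_el, width], masses, locs])


def _unpack(x, n_ev):
    return x[0], x[1], x[2], x[3:3 + n_ev], x[3 + n_ev:]


def _kernel_and_slope(u, width, k_el):
    """Kernel K(u) and its derivative dK/du (both branches of the stable
    evaluation)."""
    u = np.asarray(u, dtype=float)
    b = (k_el * width**2 - u) / (width * math.sqrt(2.0))
    tail = b < -20.0
    bs = np.where(tail, 0.0, b)
    g = np.exp(-(u**2) / (2.0 * width**2))
    ex = erfcx(bs)
    k_safe = 0.5 * ex * g
    dex = 2.0 * bs * ex - 2.0 / math.sqrt(math.pi)  # erfcx'
    db = -1.0 / (width * math.sqrt(2.0))
    dk_safe = 0.5 * g * (dex * db - ex * u / width**2)
    decay = np.exp(np.minimum(k_el * (k_el * width**2 / 2.0 - u), 700.0))
    kk = np.where(tail, decay, k_safe)
    dk = np.where(tail, -k_el * decay, dk_safe)
    return kk, dk


def _fit_once(t, y, w, baseline, k_el, width, masses, locs, lloq_floor):
    n_ev = len(masses)
    x0 = _pack(baseline, k_el, width, masses, locs)
    ymax = max(y.max(), lloq_floor)
    lo = np.concatenate([[0.0, 0.2, 0.02], np.zeros(n_ev),
                         np.full(n_ev, t[0] - 2.0)])
    hi = np.concatenate([[ymax, 30.0, 1.5], np.full(n_ev, 100.0 * ymax),
                         np.full(n_ev, t[-1] + 0.5)])
    x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)

    def resid(x):
        b, k, wd, m, l = _unpack(x, n_ev)
        return (_model(t, b, k, wd, m, l) - y) * w

    def jac(x):
        b, k, wd, m, l = _unpack(x, n_ev)
        J = np.empty((t.size, x.size))
        J[:, 0] = w
        # elimination rate and width columns by forward differences
        for col, idx in ((1, 1), (2, 2)):
            step = max(abs(x[idx]), 0.1) * 1e-6
            xp = x.copy()
            xp[idx] += step
            J[:, col] = (resid(xp) - resid(x)) / step
        for j in range(n_ev):
            kk, dk = _kernel_and_slope(t - l[j], wd, k)
            J[:, 3 + j] = kk * w
            J[:, 3 + n_ev + j] = -m[j] * dk * w
        return J

    res = least_squares(resid, x0, jac=jac, bounds=(lo, hi), method="trf",
                        xtol=1e-9, ftol=1e-9, max_nfev=200)
    return res


def _noise_s2(res, uncensored):
    """Residual variance for the significance tests, from uncensored points
    only: LLOQ-substituted stretches are exactly constant and would bias the
    variance (and every test) downward."""
    r = res.fun[uncensored] if uncensored is not None else res.fun
    dof = max(r.size - res.x.size, 1)
    return float(np.sum(r * r)) / dof, dof


def _mass_pvalues(res, n_ev, uncensored=None):
    """One-sided p-values that each event mass exceeds zero, from the
    asymptotic covariance of the weighted least-squares fit."""
    if n_ev == 0:
        return np.array([])
    s2, dof = _noise_s2(res, uncensored)
    jtj = res.jac.T @ res.jac
    cov = s2 * np.linalg.pinv(jtj, rcond=1e-12)
    se = np.sqrt(np.maximum(np.diag(cov)[3:3 + n_ev], 1e-300))
    tstat = res.x[3:3 + n_ev] / se
    return stats.t.sf(tstat, dof)


def _ftest_pvalue(ssr_without, ssr_with, s2_with, dof2, df_event=2):
    """Partial F-test for one event (mass + location).

    The mass t-test loses power when an event's mass is collinear with its
    location (a pulse centred outside the sampling window, or two heavily
    overlapping pulses); the sum-of-squares drop is robust to that, so an
    event is retained when either test is significant.
    """
    if s2_with <= 0:
        return 0.0
    f = ((ssr_without - ssr_with) / df_event) / s2_with
    if f <= 0:
        return 1.0
    return float(stats.f.sf(f, df_event, dof2))


def _candidate_location(t, y, fitted, w, locs, interval, banned):
    r = np.maximum((y - fitted) * w, 0.0)
    if r.size >= 3:  # 3-point moving average, robust to single-point noise
        r = np.convolve(r, np.ones(3) / 3.0, mode="same")
    # only residual peaks clearly above the current noise floor are worth
    # testing; this keeps the procedure from chasing numerical dust on
    # noise-free profiles
    rms = math.sqrt(float(np.mean(((y - fitted) * w) ** 2)))
    floor = max(0.06, min(0.8 * rms, 0.4))
    order = np.argsort(r)[::-1]
    for i in order:
        if r[i] <= floor:
            return None
        ti = t[i]
        if any(abs(ti - b) < 0.75 * interval for b in banned):
            continue
        if any(abs(ti - l) < 0.75 * interval for l in locs):
            continue
        return ti
    return None


def deconvolve(series: UniformSeries, init_width: float = 1.0 / 6.0,
               init_halflife: float = 0.25, alpha: float = 0.05,
               max_cycles: int = 50, lloq: float = 0.05) -> DeconvolutionFit:
    """Insert-test-remove deconvolution of one uniform hormone series.

    Residuals are weighted by ``1/max(y, lloq)`` (proportional assay error).
    The procedure alternates candidate insertion at the largest smoothed
    positive residual with removal of events whose mass loses one-sided
    significance at ``alpha``, refitting baseline, elimination rate, common
    pulse width, and all event masses/locations after every change.
    """
    t, y = series.times, series.values
    if t.size < 6:
        raise ValueError("series too short to deconvolve (need >= 6 points)")
    w = 1.0 / np.maximum(y, lloq)
    unc = y > lloq * (1.0 + 1e-9)  # LLOQ-substituted points carry no noise

    def _ssr(r):
        return float(np.sum(r.fun[unc] ** 2))
    interval = series.interval
    max_events = max(t.size // 3, 1)

    k0 = math.log(2.0) / init_halflife
    width = init_width
    baseline, k_el = float(np.percentile(y, 10)), k0
    masses: list[float] = []
    locs: list[float] = []
    res = None
    converged = False

    # all-constant series: nothing to find
    if np.ptp(y) < 1e-12:
        fitted = np.full_like(y, y[0])
        return DeconvolutionFit(basal_rate=float(y[0] * k0), elimination_rate=k0,
                                events=[], series=series, fitted=fitted,
                                residual_variance=0.0, converged=True,
                                baseline=float(y[0]))

    seen_signatures: set[tuple] = set()
    for _cycle in range(max_cycles):
        changed = False
        banned: list[float] = []
        # insertion phase
        while len(masses) < max_events:
            fitted = _model(t, baseline, k_el, width,
                            np.asarray(masses), np.asarray(locs))
            ssr_now = (_ssr(res) if res is not None
                       else float(np.sum((((y - fitted) * w) ** 2)[unc])))
            cand = _candidate_location(t, y, fitted, w, locs, interval, banned)
            if cand is None:
                break
            i = int(np.argmin(np.abs(t - cand)))
            peak = max(y[i] - fitted[i], y[i] * 0.1, lloq)
            trial_masses = masses + [peak]
            trial_locs = locs + [cand]
            trial_res = _fit_once(t, y, w, baseline, k_el, width,
                                  trial_masses, trial_locs, lloq)
            b, k, wd, m, l = _unpack(trial_res.x, len(trial_masses))
            pvals = _mass_pvalues(trial_res, len(trial_masses), unc)
            s2_tr, dof_tr = _noise_s2(trial_res, unc)
            p_f = _ftest_pvalue(ssr_now, _ssr(trial_res), s2_tr, dof_tr)
            # the F route answers many sequential looks; hold it to a
            # stricter level than the single-look t-test
            if pvals[-1] < alpha or p_f < alpha / 2.0:
                res = trial_res
                baseline, k_el, width = b, k, wd
                masses, locs = list(m), list(l)
                changed = True
            else:
                banned.append(cand)
        # removal phase
        while masses:
            if res is None:
                res = _fit_once(t, y, w, baseline, k_el, width, masses, locs, lloq)
            pvals = _mass_pvalues(res, len(masses), unc)
            order = np.argsort(pvals)[::-1]
            removed = False
            for worst in order:
                if pvals[worst] < alpha:
                    break
                kept_m = [mm for j, mm in enumerate(masses) if j != worst]
                kept_l = [ll for j, ll in enumerate(locs) if j != worst]
                res_wo = _fit_once(t, y, w, baseline, k_el, width,
                                   kept_m, kept_l, lloq) if kept_m else None
                ssr_wo = (_ssr(res_wo) if res_wo is not None
                          else float(np.sum((((y - np.median(y)) * w) ** 2)[unc])))
                s2_w, dof_w = _noise_s2(res, unc)
                p_f = _ftest_pvalue(ssr_wo, _ssr(res), s2_w, dof_w)
                if p_f < alpha / 2.0:  # the event carries real sum-of-squares
                    continue
                masses, locs = kept_m, kept_l
                res = res_wo
                if res is not None:
                    baseline, k_el, width, m, l = _unpack(res.x, len(masses))
                    masses, locs = list(m), list(l)
                changed = True
                removed = True
                break
            if not removed:
                break
        if not changed:
            converged = True
            break
        sig = tuple(np.round(sorted(locs), 3))
        if sig in seen_signatures:  # insert/remove oscillation: stop here
            converged = True
            break
        seen_signatures.add(sig)

    if res is not None:
        baseline, k_el, width, m, l = _unpack(res.x, len(masses))
        masses, locs = list(m), list(l)
    fitted = _model(t, baseline, k_el, width, np.asarray(masses), np.asarray(locs))
    resvar = float(np.mean(((y - fitted) * w) ** 2))
    order = np.argsort(locs)
    events = [SecretionEvent(float(locs[i]), float(masses[i]), float(width))
              for i in order if masses[i] > 0]
    return DeconvolutionFit(basal_rate=float(baseline * k_el),
                            elimination_rate=float(k_el), events=events,
                            series=series, fitted=fitted,
                            residual_variance=resvar, converged=converged,
                            baseline=float(baseline))


# --------------------------------------------------------------------------
# gap augmentation and pulse statistics
# --------------------------------------------------------------------------


def augment_gaps(fit: DeconvolutionFit, threshold_min: float = 300.0
                 ) -> DeconvolutionFit:
    """Insert one flagged event at the midpoint of every inter-pulse gap
    longer than ``threshold_min`` minutes.

    Applied once per original gap (not recursively), to placebo and treated
    profiles alike, so that potentially fully inhibited pulses inform the
    maximal-effect end of the concentration-effect curve.  Idempotent as long
    as the threshold exceeds half of every original gap.
    """
    originals = sorted(fit.original_events, key=lambda e: e.location)
    if len(originals) < 2:
        return fit
    threshold_h = threshold_min / 60.0
    new_events = list(fit.events)
    for a, b in zip(originals, originals[1:]):
        gap = b.location - a.location
        if gap > threshold_h:
            mid = (a.location + b.location) / 2.0
            if any(e.augmented and abs(e.location - mid) < 1e-9 for e in new_events):
                continue
            new_events.append(SecretionEvent(mid, float("nan"), float("nan"),
                                             augmented=True))
    new_events.sort(key=lambda e: e.location)
    return replace(fit, events=new_events)


def pulse_frequency_test(counts_by_group: pd.DataFrame,
                         reference: str | None = None) -> pd.DataFrame:
    """Poisson log-linear comparison of per-profile pulse counts.

    ``counts_by_group`` needs columns ``group`` and ``count`` and optionally
    ``duration`` (h, used as a log offset; default 1 for all profiles).
    Returns one row per non-reference group with the rate ratio and the Wald
    p-value against the reference (first group by default).
    """
    df = counts_by_group.copy()
    if not {"group", "count"}.issubset(df.columns):
        raise ValueError("need columns 'group' and 'count'")
    groups = list(pd.unique(df["group"]))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if reference is None:
        reference = groups[0]
    if df.loc[df["group"] == reference, "count"].sum() == 0:
        raise ValueError("reference group has zero total pulse count")
    duration = df["duration"].to_numpy(float) if "duration" in df else np.ones(len(df))
    x = pd.get_dummies(df["group"], dtype=float)
    cols = [g for g in groups if g != reference]
    exog = _sm_api.add_constant(x[cols], has_constant="add")
    model = _sm_api.GLM(df["count"].to_numpy(float), exog,
                        family=_sm_api.families.Poisson(),
                        offset=np.log(duration))
    fit = model.fit()
    out = pd.DataFrame({
        "group": cols,
        "rate_ratio": np.exp(fit.params[1:].to_numpy()),
        "p_value": fit.pvalues[1:].to_numpy(),
    })
    return out.set_index("group")


def interval_summary(fits: Sequence[DeconvolutionFit]) -> dict[str, float]:
    """Median, quartiles, and 95th percentile (minutes) of the pooled
    inter-pulse interval distribution, augmented events excluded."""
    intervals = []
    for f in fits:
        locs = sorted(e.location for e in f.original_events)
        intervals.extend(np.diff(locs) * 60.0)
    if not intervals:
        raise ValueError("no inter-pulse intervals in the pooled set")
    arr = np.asarray(intervals)
    q25, med, q75, p95 = np.percentile(arr, [25, 50, 75, 95])
    return {"median": float(med), "q25": float(q25), "q75": float(q75),
            "p95": float(p95), "n_intervals": int(arr.size)}
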