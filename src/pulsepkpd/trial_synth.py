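"""Virtual phase-1 trial generator.

Emulates a single/multiple ascending dose (S.A.D./M.A.D.) study in healthy
volunteers: cohorts of 8 (6 active, 2 placebo), subcutaneous doses of
0.1-1.5 mg single dose, 1.2 mg q.d. or 0.8/1.0 mg b.i.d. at 8 h/16 h
intervals, with dense 20-min hormone sampling windows on day 1 (S.A.D.) or
days 7 and 12 (M.A.D.).  Drug concentrations come from a two-compartment PK
model with first-order absorption and combined linear and Michaelis-Menten
elimination; GH profiles are pulsatile with log-normally varying pulse
amplitudes and a 0.05 ng/mL lower limit of quantification; PRL profiles carry
the circadian pool-model structure.  Observations receive proportional assay
noise.

All clock times are normalized so that 0 = 6 a.m.; doses are given at 8 a.m.
(normalized 2 h), with the second daily b.i.d. dose 8 h later.  Output is a
NONMEM-style long-format event table (ID, OCC, TIME, TAD, DV, DVID, AMT,
EVID, MDV, BLQ).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .structural_models import (
    DrugInput,
    GHParams,
    PRLParams,
    effect_compartment,
    emax_factor,
    gh_concentration,
    prl_concentration,
)

__all__ = [
    "DoseEvent",
    "SamplingSchedule",
    "StudyDesign",
    "PKConfig",
    "VirtualSubject",
    "GHPopulation",
    "PRLPopulation",
    "Trial",
    "COHORTS",
    "build_design",
    "simulate_pk",
    "generate_pulse_times",
    "simulate_trial",
    "apply_lloq",
]

LLOQ_GH = 0.05  # ng/mL
DOSE_CLOCK = 2.0  # first daily dose at 8 a.m. = 2 h after the 6 a.m. anchor
DVID_DRUG, DVID_GH, DVID_PRL = 1, 2, 3

#: log-normal renewal law for GH inter-pulse intervals, calibrated so the
#: median is 74 min and the quartiles 44 and 160 min
PULSE_INTERVAL_MEDIAN_MIN = 74.0
PULSE_INTERVAL_LOG_SD = (np.log(160.0) - np.log(44.0)) / (2.0 * 0.6744897501960817)


# --------------------------------------------------------------------------
# design types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseEvent:
    """One subcutaneous dose: ``time`` in hours since first dose, ``amount``
    in mg."""

    time: float
    amount: float
    route: str = "sc"

    def __post_init__(self):
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")


@dataclass(frozen=True)
class SamplingSchedule:
    """One hormone-sampling occasion.

    Offsets are hours relative to that day's first dose; the base grid runs
    every ``interval`` hours, ``extra_points`` adds the early PK-driven
    post-dose samples (15/30/60 min on S.A.D. day 1).
    """

    occasion_day: int
    start_offset: float
    end_offset: float
    interval: float = 1.0 / 3.0
    extra_points: tuple[float, ...] = ()

    def __post_init__(self):
        if self.interval <= 0:
            raise ValueError("sampling interval must be positive")
        if self.start_offset >= self.end_offset:
            raise ValueError("sampling window must have positive length")

    @property
    def occasion(self) -> int:
        return {1: 1, 7: 2, 12: 3}[self.occasion_day]

    def times(self, day_dose_time: float) -> np.ndarray:
        """Sample times on the trial clock given that day's first-dose time.

        When early PK-driven points are present they replace the base grid
        during the first post-dose hour (the trial followed the PK sampling
        schedule there instead of the 20-min grid).
        """
        n = int(round((self.end_offset - self.start_offset) / self.interval))
        base = day_dose_time + self.start_offset + self.interval * np.arange(n + 1)
        if self.extra_points:
            rel = base - day_dose_time
            base = base[(rel <= 1e-9) | (rel >= 1.0 - 1e-9)]
        extra = day_dose_time + np.asarray(self.extra_points, dtype=float)
        return np.union1d(np.round(base, 10), np.round(extra, 10))


@dataclass(frozen=True)
class StudyDesign:
    name: str
    part: str  # 'sad' | 'mad'
    doses: tuple[DoseEvent, ...]
    schedules: tuple[SamplingSchedule, ...]
    dose_clock: float = DOSE_CLOCK

    def __post_init__(self):
        t = [d.time for d in self.doses]
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("dose times must be strictly increasing")

    @property
    def is_placebo(self) -> bool:
        return not self.doses

    def without_doses(self) -> "StudyDesign":
        return replace(self, name=self.name + "/placebo", doses=())

    def day_dose_time(self, occasion_day: int) -> float:
        """Trial-clock time of the (nominal) first dose on a given day."""
        return 24.0 * (occasion_day - 1)

    def sample_times(self) -> dict[int, np.ndarray]:
        return {s.occasion: s.times(self.day_dose_time(s.occasion_day))
                for s in self.schedules}


class DesignError(KeyError):
    """Unknown cohort identifier."""


def _sad_schedule() -> tuple[SamplingSchedule, ...]:
    return (SamplingSchedule(1, -2.0, 12.0, extra_points=(0.25, 0.5, 1.0)),)


def _mad_schedule() -> tuple[SamplingSchedule, ...]:
    return (SamplingSchedule(7, -1.0, 11.0), SamplingSchedule(12, -1.0, 11.0))


def _mad_doses(amount: float, bid: bool, days: int = 13) -> tuple[DoseEvent, ...]:
    doses = []
    for d in range(days):
        doses.append(DoseEvent(24.0 * d, amount))
        if bid:
            doses.append(DoseEvent(24.0 * d + 8.0, amount))  # 8 h then 16 h gap
    return tuple(doses)


def _build_cohorts() -> dict[str, StudyDesign]:
    designs = {}
    for amt in (0.1, 0.4, 0.8, 1.2, 1.5):
        name = f"{amt:g} mg s.a.d."
        designs[name] = StudyDesign(name, "sad", (DoseEvent(0.0, amt),), _sad_schedule())
    designs["1.2 mg q.d."] = StudyDesign("1.2 mg q.d.", "mad",
                                         _mad_doses(1.2, bid=False), _mad_schedule())
    designs["0.8 mg b.i.d."] = StudyDesign("0.8 mg b.i.d.", "mad",
                                           _mad_doses(0.8, bid=True), _mad_schedule())
    designs["1.0 mg b.i.d."] = StudyDesign("1.0 mg b.i.d.", "mad",
                                           _mad_doses(1.0, bid=True), _mad_schedule())
    designs["placebo"] = StudyDesign("placebo", "sad", (), _sad_schedule())
    designs["placebo m.a.d."] = StudyDesign("placebo m.a.d.", "mad", (), _mad_schedule())
    return designs


COHORTS = _build_cohorts()


def _normalize_name(name: str) -> str:
    s = name.lower().strip()
    for a, b in (("sad", "s.a.d."), ("mad", "m.a.d."), ("qd", "q.d."),
                 ("bid", "b.i.d."), ("-", " "), ("_", " ")):
        s = s.replace(a, b)
    s = re.sub(r"(\d)\s*mg", r"\1 mg", s)
    s = " ".join(s.split())
    if s and s[0].isdigit() and "mg" not in s:
        s = s.replace(" ", " mg ", 1)
    return s


def build_design(name: str) -> StudyDesign:
    """Look up one of the published cohorts (or a placebo arm) by name.

    Accepts loose spellings such as ``"1.0mg-bid"`` or ``"1.5 mg S.A.D."``.
    """
    for key in (name, _normalize_name(name)):
        if key in COHORTS:
            return COHORTS[key]
    raise DesignError(
        f"unknown cohort {name!r}; known cohorts: {sorted(COHORTS)}")


# --------------------------------------------------------------------------
# pharmacokinetics
# --------------------------------------------------------------------------


@dataclass
class PKConfig:
    """Two-compartment PK with first-order absorption and combined linear /
    Michaelis-Menten elimination.

    The published PK analysis of this compound is a separate model whose
    numbers are not reproduced here; these defaults are illustrative values
    chosen so that the studied dose range straddles the pharmacodynamic
    EC50s (the 0.1 mg peak sits below the GH EC50 and 1.5 mg deep in
    saturation — a dose range that cannot leave the effect curve's rising
    part unsampled) and so that individual concentration-time profiles vary
    between subjects as they do in a real trial.  Supply study-specific
    values for any quantitative PK claim.
    """

    ka: float = 1.0          # /h
    vc: float = 100.0        # L
    vp: float = 150.0        # L
    q: float = 10.0          # L/h
    cl: float = 40.0         # L/h
    vmax: float = 150.0      # µg/h
    km: float = 1.0          # µg/L
    iiv_cl: float = 0.09     # log-normal variance on CL (30% CV)
    iiv_vc: float = 0.04     # log-normal variance on Vc (20% CV)

    def __post_init__(self):
        if min(self.ka, self.vc, self.vp, self.q, self.cl, self.km) <= 0:
            raise ValueError("PK parameters must be strictly positive")
        if self.vmax < 0 or self.iiv_cl < 0 or self.iiv_vc < 0:
            raise ValueError("vmax and variances must be nonnegative")


def simulate_pk(config: PKConfig, doses: Sequence[DoseEvent], times,
                rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    """Central-compartment drug concentration (µg/L) at ``times`` (h).

    Doses (mg) enter a depot compartment (converted to µg); the system is
    integrated piecewise between dose events with a stiff-capable solver.
    With ``vmax = 0`` the model is linear and superposition holds.
    """
    times = np.asarray(times, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted")
    if not doses:
        return np.zeros_like(times)

    def rhs(t, y):
        ad, ac, ap = y
        c = ac / config.vc
        cper = ap / config.vp
        elim = config.cl * c
        if config.vmax > 0:
            elim += config.vmax * c / (config.km + c)
        dad = -config.ka * ad
        dac = config.ka * ad - elim - config.q * (c - cper)
        dap = config.q * (c - cper)
        return [dad, dac, dap]

    dose_times = np.array([d.time for d in doses])
    t_end = max(times.max() if times.size else dose_times[-1], dose_times[-1]) + 1e-9
    breaks = np.concatenate([dose_times, [t_end]])
    y = np.zeros(3)
    out = np.full(times.shape, 0.0)
    out[times < dose_times[0]] = 0.0
    for i, dose in enumerate(doses):
        y[0] += dose.amount * 1000.0  # mg -> µg
        t0, t1 = breaks[i], breaks[i + 1]
        mask = (times >= t0) & (times < t1) if i < len(doses) - 1 else \
            (times >= t0) & (times <= t_end)
        t_eval = times[mask]
        sol = solve_ivp(rhs, (t0, t1), y, t_eval=t_eval if t_eval.size else None,
                        method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"PK integration failed on [{t0}, {t1}]: {sol.message}")
        if t_eval.size:
            out[mask] = sol.y[1] / config.vc
        # advance state to segment end
        sol_end = solve_ivp(rhs, (t0, t1), y, method="LSODA", rtol=rtol, atol=atol)
        y = sol_end.y[:, -1].copy()
    return np.maximum(out, 0.0)


def pk_profile(config: PKConfig, doses: Sequence[DoseEvent], t_end: float,
               grid_step: float = 0.1) -> DrugInput:
    """Tabulate the PK curve on a uniform grid as a :class:`DrugInput`."""
    if not doses:
        return DrugInput.zero(0.0, max(t_end, 1.0))
    t0 = doses[0].time
    grid = np.arange(t0, t_end + grid_step, grid_step)
    conc = simulate_pk(config, doses, grid)
    return DrugInput(grid, conc, first_dose_time=t0)


# --------------------------------------------------------------------------
# virtual population
# --------------------------------------------------------------------------


@dataclass
class GHPopulation:
    """Population GH model: typical values plus variance components.

    ``omega2_*`` are inter-individual log-normal variances; ``bov2_*`` are
    between-occasion variances (one independent draw per sampling day);
    ``omega2_amplitude_n`` is the pulse-to-pulse amplitude variance within an
    individual; ``sigma2`` the proportional residual variance.
    """

    typical: GHParams = field(default_factory=GHParams)
    omega2_baseline: float = 0.0288
    omega2_width: float = 0.0434
    omega2_k_el: float = 0.225
    omega2_amplitude_n: float = 3.46
    bov2_width: float = 0.104
    bov2_k_el: float = 0.00775
    sigma2: float = 0.0247

    def variances(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("omega2_baseline", "omega2_width", "omega2_k_el",
                 "omega2_amplitude_n", "bov2_width", "bov2_k_el", "sigma2")}

    def validated(self) -> "GHPopulation":
        if any(v < 0 for v in self.variances().values()):
            raise ValueError("variance components must be nonnegative")
        self.typical.validated()
        return self


@dataclass
class PRLPopulation:
    typical: PRLParams = field(default_factory=PRLParams)
    omega2_k_s: float = 0.068
    omega2_amp24: float = 0.57
    omega2_amp12: float = 0.87
    sigma2: float = 0.049
    #: redraw limit on |a24|+|a12| keeping the release rate positive
    amplitude_sum_cap: float = 0.95

    def variances(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("omega2_k_s", "omega2_amp24", "omega2_amp12", "sigma2")}

    def validated(self) -> "PRLPopulation":
        if any(v < 0 for v in self.variances().values()):
            raise ValueError("variance components must be nonnegative")
        self.typical.validated()
        return self


@dataclass
class CovariateModel:
    """Independent truncated-normal covariate generator (healthy male
    volunteers; means/SDs configurable, values clipped to the stated range)."""

    age: tuple[float, float, float, float] = (30.0, 8.0, 18.0, 55.0)
    weight: tuple[float, float, float, float] = (78.0, 10.0, 55.0, 110.0)
    height: tuple[float, float, float, float] = (180.0, 7.0, 160.0, 205.0)

    def draw(self, rng: np.random.Generator) -> dict[str, float]:
        out = {}
        for name in ("age", "weight", "height"):
            mean, sd, lo, hi = getattr(self, name)
            x = rng.normal(mean, sd)
            while not lo <= x <= hi:
                x = rng.normal(mean, sd)
            out[name] = x
        out["bmi"] = out["weight"] / (out["height"] / 100.0) ** 2
        # Boer lean-body-mass formula for men
        out["lbm"] = 0.407 * out["weight"] + 0.267 * out["height"] - 19.2
        return out


@dataclass
class VirtualSubject:
    id: int
    cohort: str
    active: bool
    design: StudyDesign
    covariates: dict[str, float]
    etas: dict[str, float]
    bov: dict[str, dict[int, float]]
    pulse_times: dict[int, np.ndarray]      # per occasion, trial clock h
    pulse_etas: dict[int, np.ndarray]
    drug: DrugInput | None = None


@dataclass
class Trial:
    """A simulated trial: the event table plus the rich per-subject objects
    (pulse trains, random effects, PK curves) that generated it."""

    events: pd.DataFrame
    subjects: list[VirtualSubject]
    design_names: dict[int, str] = field(default_factory=dict)


# --------------------------------------------------------------------------
# pulse trains
# --------------------------------------------------------------------------


def generate_pulse_times(duration: float, rng: np.random.Generator,
                         start: float = 0.0,
                         median_min: float = PULSE_INTERVAL_MEDIAN_MIN,
                         log_sd: float = PULSE_INTERVAL_LOG_SD) -> np.ndarray:
    """Pulse times (h) from a log-normal renewal process on [start, start+duration).

    Inter-pulse intervals are log-normal with median ``median_min`` minutes
    and log-SD calibrated to the placebo interquartile range (44-160 min).
    """
    if duration < 0:
        raise ValueError("duration must be nonnegative")
    mu = np.log(median_min / 60.0)
    times = []
    t = start
    while True:
        t = t + float(rng.lognormal(mu, log_sd))
        if t >= start + duration:
            break
        times.append(t)
    return np.asarray(times)


def apply_lloq(values: np.ndarray, lloq: float = LLOQ_GH
               ) -> tuple[np.ndarray, np.ndarray]:
    """Substitute observations below the limit of quantification.

    Returns (censored values, below-LLOQ flags); values at or above the LLOQ
    are never altered, so the operation is idempotent.
    """
    v = np.asarray(values, dtype=float).copy()
    flag = v < lloq
    v[flag] = lloq
    return v, flag


# --------------------------------------------------------------------------
# trial simulation
# --------------------------------------------------------------------------


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    # per-subject substream: subject k is invariant to the cohort roster size
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(subject_index)]))


def _draw_prl_amp_etas(rng, pop: PRLPopulation) -> tuple[float, float]:
    t = pop.typical
    for _ in range(1000):
        e24 = rng.normal(0.0, np.sqrt(pop.omega2_amp24))
        e12 = rng.normal(0.0, np.sqrt(pop.omega2_amp12))
        if abs(t.amp24) * np.exp(e24) + abs(t.amp12) * np.exp(e12) < pop.amplitude_sum_cap:
            return e24, e12
    raise RuntimeError("could not draw circadian amplitudes below the positivity cap")


def _simulate_subject(sid: int, design: StudyDesign, active: bool,
                      pk_config: PKConfig | None,
                      gh_pop: GHPopulation | None, prl_pop: PRLPopulation | None,
                      seed: int, covmodel: CovariateModel,
                      hormones: tuple[str, ...]) -> tuple[VirtualSubject, list[dict]]:
    rng = _subject_rng(seed, sid)
    covariates = covmodel.draw(rng)
    sample_times = design.sample_times()
    occasions = sorted(sample_times)
    records: list[dict] = []

    doses = design.doses if active else ()
    drug = None
    if doses:
        iiv = {"cl": rng.normal(0, np.sqrt(pk_config.iiv_cl)) if pk_config.iiv_cl else 0.0,
               "vc": rng.normal(0, np.sqrt(pk_config.iiv_vc)) if pk_config.iiv_vc else 0.0}
        cfg = replace(pk_config, cl=pk_config.cl * np.exp(iiv["cl"]),
                      vc=pk_config.vc * np.exp(iiv["vc"]))
        t_end = max(max(t.max() for t in sample_times.values()),
                    doses[-1].time) + 12.0
        drug = pk_profile(cfg, doses, t_end)

    etas: dict[str, float] = {}
    bov: dict[str, dict[int, float]] = {}
    pulse_times: dict[int, np.ndarray] = {}
    pulse_etas: dict[int, np.ndarray] = {}

    if gh_pop is not None and "GH" in hormones:
        g = gh_pop.typical
        etas["gh_baseline"] = rng.normal(0, np.sqrt(gh_pop.omega2_baseline))
        etas["gh_width"] = rng.normal(0, np.sqrt(gh_pop.omega2_width))
        etas["gh_k_el"] = rng.normal(0, np.sqrt(gh_pop.omega2_k_el))
        bov["gh_width"] = {o: rng.normal(0, np.sqrt(gh_pop.bov2_width)) for o in occasions}
        bov["gh_k_el"] = {o: rng.normal(0, np.sqrt(gh_pop.bov2_k_el)) for o in occasions}
        for occ in occasions:
            tt = sample_times[occ]
            # pulses may start up to 2 h before the sampling window
            pt = generate_pulse_times(tt.max() - tt.min() + 2.0, rng,
                                      start=tt.min() - 2.0)
            pulse_times[occ] = pt
            pulse_etas[occ] = rng.normal(0, np.sqrt(gh_pop.omega2_amplitude_n), pt.size)
            params = replace(
                g,
                baseline=g.baseline * np.exp(etas["gh_baseline"]),
                width=g.width * np.exp(etas["gh_width"] + bov["gh_width"][occ]),
                k_el=g.k_el * np.exp(etas["gh_k_el"] + bov["gh_k_el"][occ]),
            )
            masses = g.amplitude * np.exp(pulse_etas[occ])
            pred = gh_concentration(params, pt, masses, drug, tt)
            eps = rng.normal(0, np.sqrt(gh_pop.sigma2), tt.size)
            dv, blq = apply_lloq(pred * (1.0 + eps))
            for t, v, fl in zip(tt, dv, blq):
                records.append(dict(ID=sid, OCC=occ, TIME=t + design.dose_clock,
                                    TAD=t, DV=v, DVID=DVID_GH, AMT=0.0,
                                    EVID=0, MDV=0, BLQ=int(fl)))

    if prl_pop is not None and "PRL" in hormones:
        p = prl_pop.typical
        etas["prl_k_s"] = rng.normal(0, np.sqrt(prl_pop.omega2_k_s))
        e24, e12 = _draw_prl_amp_etas(rng, prl_pop)
        etas["prl_amp24"], etas["prl_amp12"] = e24, e12
        params = replace(p, k_s=p.k_s * np.exp(etas["prl_k_s"]),
                         amp24=p.amp24 * np.exp(e24), amp12=p.amp12 * np.exp(e12))
        all_t = np.concatenate([sample_times[o] for o in occasions])
        order = np.argsort(all_t)
        pred_sorted = prl_concentration(params, drug, design.dose_clock,
                                        all_t[order])
        pred = np.empty_like(pred_sorted)
        pred[order] = pred_sorted
        eps = rng.normal(0, np.sqrt(prl_pop.sigma2), all_t.size)
        dv = pred * (1.0 + eps)
        i = 0
        for occ in occasions:
            for t in sample_times[occ]:
                records.append(dict(ID=sid, OCC=occ, TIME=t + design.dose_clock,
                                    TAD=t, DV=dv[i], DVID=DVID_PRL, AMT=0.0,
                                    EVID=0, MDV=0, BLQ=0))
                i += 1

    for d in doses:
        day = int(d.time // 24.0) + 1
        occ = 1 if day < 7 else (2 if day < 12 else 3)
        records.append(dict(ID=sid, OCC=occ,
                            TIME=d.time + design.dose_clock, TAD=d.time,
                            DV=np.nan, DVID=DVID_DRUG, AMT=d.amount,
                            EVID=1, MDV=1, BLQ=0))
    if drug is not None:
        # noiseless drug concentration records so a file-based fit can
        # reconstruct the individual PK curve
        for occ in occasions:
            tt = sample_times[occ]
            cp = drug(tt)
            for t, v in zip(tt, cp):
                records.append(dict(ID=sid, OCC=occ, TIME=t + design.dose_clock,
                                    TAD=t, DV=v, DVID=DVID_DRUG, AMT=0.0,
                                    EVID=0, MDV=0, BLQ=0))

    subject = VirtualSubject(sid, design.name, active, design, covariates,
                             etas, bov, pulse_times, pulse_etas, drug)
    return subject, records


def simulate_trial(cohorts: Sequence[tuple[str, int, int]],
                   pk_config: PKConfig | None = None,
                   gh_pop: GHPopulation | None = None,
                   prl_pop: PRLPopulation | None = None,
                   seed: int = 0,
                   hormones: tuple[str, ...] = ("GH", "PRL"),
                   covariate_model: CovariateModel | None = None) -> Trial:
    """Simulate a virtual trial.

    ``cohorts`` is a list of ``(design name, n_active, n_placebo)``; placebo
    subjects in a cohort share the cohort's sampling schedule without dose
    events.  Hormone populations default to the published parameter vectors
    when the corresponding hormone is requested.  The master ``seed`` spawns
    one substream per subject, so subject k's data are invariant to how many
    subjects follow.
    """
    if pk_config is None:
        pk_config = PKConfig()
    if gh_pop is None and "GH" in hormones:
        gh_pop = GHPopulation()
    if prl_pop is None and "PRL" in hormones:
        prl_pop = PRLPopulation()
    if gh_pop is not None:
        gh_pop.validated()
    if prl_pop is not None:
        prl_pop.validated()
    covmodel = covariate_model or CovariateModel()

    subjects: list[VirtualSubject] = []
    all_records: list[dict] = []
    design_names: dict[int, str] = {}
    sid = 0
    for name, n_active, n_placebo in cohorts:
        design = build_design(name)
        if n_active and design.is_placebo:
            raise ValueError(f"cohort {name!r} has no doses; use n_placebo")
        for active in ([True] * n_active + [False] * n_placebo):
            sid += 1
            subj, recs = _simulate_subject(
                sid, design if active else design.without_doses(), active,
                pk_config, gh_pop, prl_pop, seed, covmodel, hormones)
            subjects.append(subj)
            all_records.extend(recs)
            design_names[sid] = design.name

    events = pd.DataFrame(all_records,
                          columns=["ID", "OCC", "TIME", "TAD", "DV", "DVID",
                                   "AMT", "EVID", "MDV", "BLQ"])
    events = events.sort_values(["ID", "TIME", "EVID"],
                                kind="stable").reset_index(drop=True)
    return Trial(events, subjects, design_names)
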