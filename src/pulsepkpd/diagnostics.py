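"""Model-evaluation statistics for fitted population models.

Covers conditional weighted residuals with interaction (CWRESI), normalized
prediction distribution errors (NPDE), the prediction-corrected visual
predictive check (pcVPC, prolactin only — the timing of GH pulses differs
between subjects, so percentile bands over clock time are not meaningful for
the pulsatile GH model and such requests are refused), eta-shrinkage, and
covariate screening of empirical Bayes estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .nlme import (
    FitResult,
    ParameterSet,
    SIGMA2_FLOOR,
    PRED_FLOOR,
    SubjectData,
    _solve_inner,
    lrt,
)

__all__ = [
    "ResidualTable",
    "NPDEResult",
    "VPCResult",
    "UnsupportedDiagnosticError",
    "cwresi",
    "npde",
    "pcvpc",
    "shrinkage",
    "covariate_screen",
]


class UnsupportedDiagnosticError(ValueError):
    """The requested diagnostic is not defined for this model."""


# --------------------------------------------------------------------------
# CWRESI
# --------------------------------------------------------------------------


@dataclass
class ResidualTable:
    table: pd.DataFrame  # ID, OCC, TIME, TAD, PRED, IPRED, CWRESI, group

    def fraction_outside(self, bound: float = 2.0) -> float:
        return float((self.table.CWRESI.abs() > bound).mean())


def _residual_variances(f: np.ndarray, pset: ParameterSet) -> np.ndarray:
    s2 = max(pset.sigma2, SIGMA2_FLOOR)
    if pset.error_model == "proportional":
        fm = np.maximum(f, PRED_FLOOR)
        return s2 * fm * fm
    return np.full(f.shape, s2)


def cwresi(model, subjects: Sequence[SubjectData], fit: FitResult
           ) -> ResidualTable:
    """Conditional weighted residuals with interaction.

    The model is linearized at each subject's posterior-mode random effects:
    ``E[y] ~= f(eta_hat) - J eta_hat`` and
    ``Cov[y] ~= J Omega J' + diag(v(f(eta_hat)))`` (the interaction: the
    residual variance uses the individual prediction).  CWRESI is the
    whitened residual; under the true model it is approximately standard
    normal, so the bulk of values should fall inside [-2, 2].
    """
    pset = fit.params
    rows = []
    for s in subjects:
        eta, meta, var_eta, f_hat, _ = _solve_inner(model, s, pset.values(), pset)
        f_pop = model.predict(s, pset.values(), np.zeros(eta.size), meta)
        v = _residual_variances(f_hat, pset)
        if eta.size:
            J = model.jacobian(s, pset.values(), eta, meta, f_hat)
            cov = (J * var_eta[None, :]) @ J.T + np.diag(v)
            mean = f_hat - J @ eta
        else:
            cov = np.diag(v)
            mean = f_hat
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular conditional covariance for subject {s.id}: {exc}")
        res = solve_triangular(L, s.y - mean, lower=True)
        for i in range(s.y.size):
            rows.append(dict(ID=s.id, OCC=int(s.occ[i]), TAD=s.times[i],
                             TIME=s.times[i] + s.clock_offset,
                             DV=s.y[i], PRED=f_pop[i], IPRED=f_hat[i],
                             CWRESI=res[i], group=s.cohort))
    return ResidualTable(pd.DataFrame(rows))


# --------------------------------------------------------------------------
# NPDE
# --------------------------------------------------------------------------


@dataclass
class NPDEResult:
    table: pd.DataFrame           # ID, OCC, TAD, NPDE
    summary: pd.DataFrame         # per occasion-day: mean, var, shapiro p


def npde(model, subjects: Sequence[SubjectData], fit: FitResult,
         n_sim: int = 1000, seed: int = 0) -> NPDEResult:
    """Normalized prediction distribution errors, stratified per treatment day.

    Each subject is simulated ``n_sim`` times under the fitted population
    model; observations and simulations are decorrelated with the empirical
    simulation mean and covariance, ranked, and mapped through the inverse
    normal (mid-rank convention, clamped to ``1/(2 n_sim)`` at the
    boundaries).  Under a correct model the values are standard normal within
    each stratum.
    """
    if n_sim < 100:
        raise ValueError("need n_sim >= 100 for stable decorrelation")
    rng = np.random.default_rng(seed)
    rows = []
    for s in subjects:
        sims = np.stack([model.simulate(s, fit.params, rng)
                         for _ in range(n_sim)])
        mean = sims.mean(axis=0)
        cov = np.cov(sims, rowvar=False)
        cov = np.atleast_2d(cov) + 1e-10 * np.eye(s.y.size)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"degenerate simulation covariance for subject {s.id}")
        y_dec = np.linalg.solve(L, s.y - mean)
        # finite-simulation (Wishart) correction: the observation is
        # out-of-sample with respect to the estimated covariance, and the
        # triangular decorrelation residualizes component i on i earlier
        # components with coefficients estimated from n_sim draws, inflating
        # its variance by ~ n_sim/(n_sim - i - 2) relative to the in-sample
        # simulations it is ranked against
        idx_c = np.arange(s.y.size)
        y_dec *= np.sqrt(np.maximum(n_sim - idx_c - 2, 1) / n_sim)
        sims_dec = np.linalg.solve(L, (sims - mean).T).T
        below = (sims_dec < y_dec[None, :]).sum(axis=0)
        ties = (sims_dec == y_dec[None, :]).sum(axis=0)
        pd_ = (below + 0.5 * ties) / n_sim
        pd_ = np.clip(pd_, 1.0 / (2 * n_sim), 1.0 - 1.0 / (2 * n_sim))
        vals = stats.norm.ppf(pd_)
        for i in range(s.y.size):
            rows.append(dict(ID=s.id, OCC=int(s.occ[i]), TAD=s.times[i],
                             NPDE=vals[i], group=s.cohort))
    table = pd.DataFrame(rows)
    summ = []
    for occ, grp in table.groupby("OCC"):
        v = grp.NPDE.to_numpy()
        sw = stats.shapiro(v if v.size <= 5000 else
                           rng.choice(v, 5000, replace=False))
        summ.append(dict(OCC=occ, n=v.size, mean=float(v.mean()),
                         var=float(v.var(ddof=1)), shapiro_p=float(sw.pvalue)))
    return NPDEResult(table, pd.DataFrame(summ))


# --------------------------------------------------------------------------
# pcVPC
# --------------------------------------------------------------------------


@dataclass
class VPCResult:
    bins: pd.DataFrame
    """Per clock-time bin: observed prediction-corrected percentiles
    (p5/p50/p95), simulated median and CI bands for each percentile, n."""

    def coverage(self) -> float:
        """Fraction of observed percentile points (5th/50th/95th per bin)
        falling inside the corresponding simulated 95% band.  Each band is a
        95% interval, so ~95% coverage is expected under the true model
        (requiring all three percentiles of a bin jointly would only reach
        ~0.95^3 even then)."""
        b = self.bins
        checks = np.concatenate([
            b.obs_p5.between(b.sim_p5_lo, b.sim_p5_hi).to_numpy(),
            b.obs_p50.between(b.sim_p50_lo, b.sim_p50_hi).to_numpy(),
            b.obs_p95.between(b.sim_p95_lo, b.sim_p95_hi).to_numpy(),
        ])
        return float(checks.mean())


def pcvpc(model, subjects: Sequence[SubjectData], fit: FitResult,
          bins: int = 12, n_sim: int = 200, seed: int = 0) -> VPCResult:
    """Prediction-corrected visual predictive check over clock time.

    Observations and simulations are scaled by ``bin median PRED / PRED_ij``
    to remove inter-individual differences in the typical prediction, then
    summarized as 5th/50th/95th percentiles per clock-time bin with
    Monte-Carlo confidence bands.  Defined for the PRL model only: pcVPC is
    unsupported for pulsatile GH because pulse timing differs between
    subjects.
    """
    if getattr(model, "hormone", "?") == "GH":
        raise UnsupportedDiagnosticError("pcVPC unsupported for pulsatile GH")
    rng = np.random.default_rng(seed)
    pset = fit.params

    clock, preds, obs = [], [], []
    for s in subjects:
        var, meta = model.eta_info(s, pset)
        f_pop = model.predict(s, pset.values(), np.zeros(var.size), meta)
        clock.append((s.times + s.clock_offset) % 24.0)
        preds.append(f_pop)
        obs.append(s.y)
    clock = np.concatenate(clock)
    pred = np.concatenate(preds)
    y = np.concatenate(obs)

    edges = np.quantile(clock, np.linspace(0, 1, bins + 1))
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    which = np.clip(np.searchsorted(edges, clock, side="right") - 1, 0, bins - 1)

    sims = np.empty((n_sim, y.size))
    for r in range(n_sim):
        sims[r] = np.concatenate([model.simulate(s, pset, rng) for s in subjects])

    rows = []
    for b in range(bins):
        m = which == b
        if not np.any(m):
            continue
        med_pred = np.median(pred[m])
        corr = med_pred / np.maximum(pred[m], PRED_FLOOR)
        o5, o50, o95 = np.percentile(y[m] * corr, [5, 50, 95])
        sim_pc = sims[:, m] * corr[None, :]
        sp = np.percentile(sim_pc, [5, 50, 95], axis=1)  # (3, n_sim)
        (s5lo, s5hi), (s50lo, s50hi), (s95lo, s95hi) = [
            np.percentile(sp[i], [2.5, 97.5]) for i in range(3)]
        rows.append(dict(
            bin=b, t_lo=edges[b], t_hi=edges[b + 1], n=int(m.sum()),
            obs_p5=o5, obs_p50=o50, obs_p95=o95,
            sim_p5=np.median(sp[0]), sim_p50=np.median(sp[1]),
            sim_p95=np.median(sp[2]),
            sim_p5_lo=s5lo, sim_p5_hi=s5hi, sim_p50_lo=s50lo,
            sim_p50_hi=s50hi, sim_p95_lo=s95lo, sim_p95_hi=s95hi))
    return VPCResult(pd.DataFrame(rows))


# --------------------------------------------------------------------------
# shrinkage and covariates
# --------------------------------------------------------------------------


def shrinkage(fit: FitResult) -> dict[str, float]:
    """Eta-shrinkage per inter-individual random effect,
    ``100 * (1 - SD(EBE)/omega)`` (values above ~30% flag an uninformative
    random effect).  Effects with zero variance are reported as NaN."""
    pset = fit.params
    per_effect: dict[str, list[float]] = {}
    for sid, (eta, meta) in fit.ebes.items():
        for val, m in zip(eta, meta):
            if m[0] == "iiv":
                per_effect.setdefault(m[1], []).append(float(val))
    out = {}
    for name, omega2 in pset.omega2.items():
        vals = per_effect.get(name)
        if not vals or omega2 <= 0:
            out[name] = float("nan")
            continue
        if len(vals) < 2:
            raise ValueError("shrinkage needs at least 2 subjects")
        out[name] = 100.0 * (1.0 - np.std(vals, ddof=1) / math.sqrt(omega2))
    return out


@dataclass
class CovariateScreen:
    r2: pd.DataFrame               # effect x covariate r-squared
    flagged: list[tuple[str, str]]  # (effect, covariate) with r2 > threshold
    stepping: pd.DataFrame | None = None


def covariate_screen(fit: FitResult, covariates: pd.DataFrame,
                     threshold: float = 0.50,
                     fit_candidate: Callable | None = None,
                     alpha_forward: float = 0.05,
                     alpha_backward: float = 0.01) -> CovariateScreen:
    """Screen covariates against empirical Bayes estimates.

    ``covariates`` has one row per subject (index = subject id) with
    mean-centered or raw covariate columns (centering is applied here).
    Candidates with ``r^2 > threshold`` are flagged.  When ``fit_candidate``
    is provided — a callable ``(effect, covariate) -> FitResult`` that refits
    the model with that covariate relationship — flagged candidates go
    through forward inclusion / backward deletion by likelihood-ratio
    testing; with no flagged candidates the stepping result is empty.
    """
    per_effect: dict[str, dict[int, float]] = {}
    for sid, (eta, meta) in fit.ebes.items():
        for val, m in zip(eta, meta):
            if m[0] == "iiv":
                per_effect.setdefault(m[1], {})[sid] = float(val)

    records = []
    flagged = []
    for eff, by_id in per_effect.items():
        ids = sorted(by_id)
        ebe = np.array([by_id[i] for i in ids])
        for covname in covariates.columns:
            x = covariates.loc[ids, covname].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                records.append(dict(effect=eff, covariate=covname,
                                    r2=float("nan"), note="constant covariate"))
                continue
            xc = x - x.mean()
            r = np.corrcoef(xc, ebe)[0, 1]
            r2 = float(r * r)
            records.append(dict(effect=eff, covariate=covname, r2=r2, note=""))
            if r2 > threshold:
                flagged.append((eff, covname))

    stepping = None
    if fit_candidate is not None:
        steps = []
        included: list[tuple[str, str]] = []
        current = fit
        for eff, covname in flagged:  # forward inclusion at alpha_forward
            cand = fit_candidate(eff, covname)
            cmp_ = lrt(current, cand, df=1, alpha=alpha_forward)
            steps.append(dict(stage="forward", effect=eff, covariate=covname,
                              delta_ofv=cmp_.delta_ofv,
                              included=cmp_.significant))
            if cmp_.significant:
                included.append((eff, covname))
                current = cand
        for eff, covname in list(included):  # backward deletion at alpha_backward
            cand = fit_candidate(eff, covname)
            cmp_ = lrt(current, cand, df=1, alpha=alpha_backward)
            steps.append(dict(stage="backward", effect=eff, covariate=covname,
                              delta_ofv=cmp_.delta_ofv,
                              included=cmp_.significant))
            if not cmp_.significant:
                included.remove((eff, covname))
        stepping = pd.DataFrame(steps)

    return CovariateScreen(pd.DataFrame(records), flagged, stepping)
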