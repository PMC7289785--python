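# pulsepkpd

Population PK/PD modelling of the endogenous **growth hormone (GH)** and
**prolactin (PRL)** lowering effects of a somatostatin–dopamine chimera
("dopastatin") in a phase-1 single/multiple ascending dose trial — built as a
reusable, fully synthetic-data-driven Python package.

GH is secreted in discrete pulses whose timing and size vary enormously
between and within individuals; simple summary statistics (mean, AUC) throw
that structure away. The approach implemented here keeps it:

1. **Deconvolution** decomposes each 20-min-sampled GH profile into a basal
   secretion rate, a first-order elimination rate and a set of Gaussian
   secretion events (insert–test–remove with per-event significance tests).
2. The **structural GH model** rebuilds the profile from those pulse
   locations: secretion `S(t) = k_base + Σ_j m_j·Emax(Ce(T_j))·φ(t; T_j, w)`
   feeding `dC/dt = S(t) − k_el·C`, where the drug inhibits each pulse mass
   through an inhibitory `Emax = 1 + E_max·Ce/(EC50 + Ce)` factor driven by an
   effect compartment `dCe/dt = k_e0(Cp − Ce)`.
3. The **PRL pool model** has synthesis `k_s` into a precursor pool, release
   `k_r` into plasma modulated by two circadian cosines
   (`DIU = Θ_amp·cos(2π(t−Θ_phase)/period)`, periods 24 h and 12 h, clock
   normalized to 6 a.m.), direct plasma-drug Emax inhibition of release, and a
   synthesis decline `I(t) = x·Θ_slope/(1+x·Θ_slope)` driven by cumulative
   exposure `x` (mg·h/L).
4. A **FOCE-style mixed-effects estimator** (Laplace approximation at the
   posterior mode of the random effects, with interaction) fits population
   parameters with log-normal inter-individual, between-occasion and
   per-pulse variability and proportional residual error, following the
   sequential placebo-first protocol; likelihood-ratio tests use the
   ΔOFV ≥ 6.64 (χ², df 1, p < 0.01) criterion.
5. **Diagnostics**: CWRESI, NPDE (per treatment day), prediction-corrected
   VPC over clock time (PRL only — pulse timing makes a pcVPC meaningless
   for GH, and such requests are refused), η-shrinkage, covariate screening,
   nonparametric bootstrap.

Because the clinical data are not public, the package ships a **virtual
trial generator** that emulates the published design: cohorts of 8
(6 active : 2 placebo), 0.1–1.5 mg single doses, 1.2 mg q.d. and 0.8/1.0 mg
b.i.d. (8 h/16 h spacing), 20-min hormone sampling windows on days 1/7/12,
log-normal pulse-amplitude variability, a 0.05 ng/mL GH LLOQ (values below
are substituted, not censored) and a two-compartment PK driver with combined
linear and Michaelis–Menten elimination. Every stage of the analysis is
exercisable end to end on these virtual trials.

## Worked example

```python
import pulsepkpd as pk

# a virtual trial: 2 placebo + 6 active on 1.0 mg b.i.d.
trial = pk.simulate_trial([("placebo", 0, 2), ("1.0 mg b.i.d.", 6, 0)],
                          seed=1)
print(trial.events.head(3).to_string(index=False))

# deconvolve one GH profile (subject 1, day 1)
gh = trial.events.query("ID == 1 and DVID == 2 and OCC == 1")
series = pk.regularize_grid(gh.TAD.to_numpy(), gh.DV.to_numpy(), dose_time=0.0)
fit = pk.augment_gaps(pk.deconvolve(series))
print(f"k_el = {fit.elimination_rate:.2f}/h, "
      f"{len(fit.events)} secretion events")

# inter-pulse interval statistics for that profile
stats = pk.interval_summary([fit])
print({k: round(v, 1) for k, v in stats.items()})
```

prints (numbers from this exact seed):

```
 ID  OCC     TIME       TAD        DV  DVID  AMT  EVID  MDV  BLQ
  1    1 0.000000 -2.000000  0.077249     2  0.0     0    0    0
  1    1 0.000000 -2.000000 13.439060     3  0.0     0    0    0
  1    1 0.333333 -1.666667  0.099257     2  0.0     0    0    0
k_el = 4.40/h, 13 secretion events
{'median': 61.1, 'q25': 38.4, 'q75': 81.9, 'p95': 125.9, 'n_intervals': 12}
```

Subject 1 drew an individual elimination rate of 4.15/h (the population value
is 3.6/h with 50% CV), so the deconvolution estimate of 4.40/h is within 6%
of this subject's truth; 9 of the 13 events match generated pulses, and one
profile's dozen inter-pulse intervals scatter around the population median
of 74 min.

A population fit then runs as

```python
subjects = pk.nlme.subjects_from_trial(trial, "PRL")
result = pk.fit(pk.PRLModel(), subjects, pk.PRLModel.default_parameters())
print(result.params.values())
```

or from the shell:

```bash
pulsepkpd simulate --design "placebo 0 2" --design "1.0 mg b.i.d. 6 0" \
    --seed 1 --out trial.csv
pulsepkpd deconvolve trial.csv --hormone GH --alpha 0.05 --out pulses.csv
pulsepkpd fit trial.csv --pulses pulses.csv --model gh --stage placebo --out fit.json
pulsepkpd diagnose fit.json trial.csv --which cwresi,shrinkage --out report/
```

The event-table CSV is NONMEM-style (`ID, OCC, TIME, TAD, DV, DVID, AMT,
EVID, MDV, BLQ`; `DVID` 1 = drug µg/L, 2 = GH ng/mL, 3 = PRL ng/mL; clock
normalized so 0 = 6 a.m.).

## Layout

| module | contents |
| --- | --- |
| `trial_synth` | study designs, PK simulation, pulse-train generator, virtual populations, event tables |
| `deconv` | grid regularization, insert–test–remove deconvolution, gap augmentation, pulse-frequency GLM |
| `structural_models` | GH pulse/elimination model, PRL pool model, Emax/circadian/exposure building blocks |
| `nlme` | FOCE-style objective, fitting, LRT, covariance step, bootstrap |
| `diagnostics` | CWRESI, NPDE, pcVPC, shrinkage, covariate screening |
| `cli_io` / `cli` | dataset I/O, config, pipeline, `pulsepkpd` command |
| `workflows` | end-to-end simulation/re-estimation experiments |

See `docs/methods.md` for the modelling assumptions, numerical choices and
known limitations.
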