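# meropk

Population pharmacokinetics and dosing simulation of **meropenem in adults on
extracorporeal membrane oxygenation (ECMO)**.

Critically ill patients on ECMO often need broad-spectrum antibiotics, and the
circuit itself (hemodilution, sequestration, altered hemodynamics) can change
drug disposition. `meropk` implements, end to end, the population-PK workflow
used to answer the practical question *"which meropenem regimen reaches the
pharmacodynamic target in these patients?"*:

- **Two-compartment IV-infusion kinetics** in closed form (single dose,
  superposition, analytic steady state, half-lives, Vss).
- **The published covariate model** for meropenem during ECMO:

  ```
  CL = θ1 · (1 + θ2 · (CRCL − 49.7))        θ1 = 7.35 L/h, θ2 = 0.0104
  Vc = θ3 · (1 + θ4 · (LPM  − 3.7))         θ3 = 17.3 L,  θ4 = 0.337
  Q  = 14.5 L/h,  Vp = 12.8 L
  ```

  with log-normal between-subject variability on CL, Vc, Vp
  (ω = 39.6 / 48.5 / 38.8 %) and combined additive + proportional residual
  error (σ_add = 0.37 mg/L, σ_prop = 4.73 %). CRCL is Cockcroft–Gault
  creatinine clearance (ml/min); LPM is the ECMO circuit flow (L/min).
- **FOCE-I estimation** (first-order conditional estimation with interaction)
  of that model from NONMEM-style datasets: objective function, fitting with
  RSEs and eta-shrinkage, likelihood-ratio model comparison, stepwise
  covariate search, and a nonparametric bootstrap.
- **Diagnostics**: conditional weighted residuals (CWRES) and the prediction-
  and variability-corrected visual predictive check (pcVPC).
- **Monte Carlo probability of target attainment (PTA)** for the carbapenem
  targets 40% fT>MIC, 100% fT>MIC and 100% fT>4×MIC (unbound fraction 0.98),
  over renal-function groups, doses, infusion durations, intervals, MIC grids
  and ECMO flow rates. A regimen is "optimal" when PTA ≥ 90%.
- **A synthetic-cohort generator** reproducing the underlying study design
  (30 subjects, single 0.5/1 g dose over 3 h, 7 samples on three fixed
  schemes, covariates matching the reported cohort summaries), so the whole
  pipeline is testable without access to the clinical data.

The intended audience is pharmacometricians and infectious-disease
researchers who want a transparent, scriptable re-implementation of this
analysis — for teaching, methodological work, or simulation studies around
ECMO dosing.

## Worked example

```python
import meropk as mp

model = mp.default_model()          # published population estimates

# typical subject at the covariate medians
p = mp.typical_params(model, mp.CovariateVector(crcl=49.7, lpm=3.7))
print(p)                            # StructuralParams(CL=7.35, Vc=17.3, Vp=12.8, Q=14.5)
print(mp.vss(p))                    # 30.1  (L)
print(mp.half_lives(p))             # (0.319, 3.132)  distribution/elimination t1/2, h

# simulate the study design and refit the model
data = mp.simulate_dataset(mp.CohortSpec(), model, seed=1)
print(data.summary())               # 30 subjects, 30 dose records,
                                    # 210 observation records (49 BLQ)
fit = mp.fit(data, model, compute_rse=False)
print(round(fit.ofv, 2), round(fit.estimates["CL"], 2))   # 509.69 8.34

# probability of target attainment: 1 g q8h over 3 h, CRCL 50-90 ml/min,
# target 100% fT>MIC at MIC 1 mg/L
res = mp.simulate_pta(
    model, (50, 90), 3.7, mp.DosingRegimen(1000, 3.0, 8.0, None),
    [mp.PDTarget(mic=1.0, fraction_pct=100)], n=1000, seed=1,
)[0]
print(round(100 * res.pta, 1), res.optimal)               # 94.1 True
```

The numbers mean: the typical patient clears 7.35 L of plasma per hour and
distributes meropenem over 30.1 L at steady state; refitting the generating
model to one synthetic cohort reproduces the typical clearance within the
sampling noise of a 30-subject study; and 94% of simulated patients with
creatinine clearance 50–90 ml/min keep free meropenem above 1 mg/L for the
entire dosing interval under 1 g q8h infused over 3 h — an "optimal" regimen
under the 90% rule.

A command-line interface wraps the same functionality:

```bash
meropk simulate-data --n 30 --seed 1 --out cohort.csv
meropk fit --data cohort.csv --out fit.json
meropk vpc --data cohort.csv --n-sim 1000 --seed 2 --out vpc.csv --plot vpc.png
meropk grid --seed 3 --out pta_grid.csv     # full regimen x MIC x target table
```

## Layout

| module | contents |
| --- | --- |
| `meropk.pk_core` | closed-form two-compartment kinetics |
| `meropk.popmodel` | covariate model, BSV, residual error |
| `meropk.synthesis` | synthetic study-cohort generator |
| `meropk.estimation` | FOCE-I objective, fitting, covariate search, bootstrap |
| `meropk.diagnostics` | CWRES, pcVPC, goodness-of-fit plots |
| `meropk.pta` | Monte Carlo target-attainment simulation |
| `meropk.io` / `meropk.cli` | NONMEM-style CSV I/O and the `meropk` command |

`docs/methods.md` describes the model, the estimation algorithm and the
numerical choices in detail.
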