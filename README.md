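# ccwdtr

Cloning–censoring–weighting evaluation of threshold-based dialysis-initiation
strategies in ICU cohorts, with a synthetic cohort generator and a
counterfactual simulation oracle for validating the estimators.

The package implements a target-trial-emulation pipeline for comparing 81
dynamic treatment regimes that prescribe starting renal replacement therapy
(RRT) when, after reaching AKI stage ≥ 2, the patient's pH falls below a
threshold, potassium reaches a threshold, or stage-3 oliguria persists for
24 h — with separate pH/potassium thresholds for oliguric and non-oliguric
patients. The estimand is 30-day ICU mortality from inclusion (ICU discharge
as competing event), plus the expected number of patients started on RRT.

## What is in here

| module | role |
| --- | --- |
| `ccwdtr.synthetic` | confounded synthetic ICU cohort generator + forced-policy oracle |
| `ccwdtr.eligibility` | KDIGO-style AKI staging, inclusion day, exclusion screening |
| `ccwdtr.regimes` | the 81-regime threshold grid and daily prescription logic |
| `ccwdtr.clone_censor` | one clone per (patient, regime); artificial censoring at first deviation |
| `ccwdtr.ipcw` | pooled logistic initiation model → inverse-probability-of-censoring weights |
| `ccwdtr.estimation` | IPC-weighted discrete-time Aalen–Johansen, IJ variance, patient bootstrap |
| `ccwdtr.evaluation` | per-regime evaluation, observed-care reference, optimal regime, k-fold CV benchmark |
| `ccwdtr.io` | CSV readers/writers, validation, YAML config, run logs |
| `ccwdtr.benchmarks` | reference simulation studies shared by tests and the acceptance report |

## Quick start (Python)

```python
import ccwdtr

params = ccwdtr.default_scenario(n_patients=2000, seed=1)
baseline, person_days = ccwdtr.generate_cohort(params)

report = ccwdtr.evaluate_all_regimes(baseline, person_days)
print(report.summary())            # observed care, optimal regime, risk difference
report.regime_table                # one row per regime: mortality, CI, RRT count

# ground truth for any regime by forced simulation
regime = ccwdtr.enumerate_regimes()[26]          # grid row 27
oracle = ccwdtr.simulate_counterfactual_cif(params, regime, n_mc=50_000, seed=2)
print(oracle.cif_death[-1])
```

## Command line

```bash
ccwdtr simulate --n-patients 2000 --seed 1 --out data/
ccwdtr stage    --baseline data/baseline.csv --person-days data/person_days.csv --out staging.csv
ccwdtr evaluate --baseline data/baseline.csv --person-days data/person_days.csv \
                --config examples/config.yaml --seed 1 --out results/
ccwdtr cv       --baseline data/baseline.csv --person-days data/person_days.csv \
                --k-folds 5 --out cv.json
ccwdtr report   --evaluations results/regime_evaluations.csv \
                --summary results/summary.json --out report/
```

The YAML config has sections `scenario`, `regimes`, `weights`, `estimation`,
`cv` (see `examples/config.yaml`); every run writes a `run_log.json` with the
seed, package versions and a config hash.

## Method sketch

1. Patients enter follow-up on the first day the combined AKI stage reaches 2
   (creatinine ratio ≥ 2.0 or absolute ≥ 4.0 mg/dl; urine output < 0.5
   ml/kg/h for a day; < 0.3 ml/kg/h over two consecutive days is stage 3).
2. Each eligible patient is cloned once per regime. A clone is censored the
   first day the regime's prescription deviates from observed care (the daily
   decision precedes that day's event).
3. A single pooled logistic model for the daily initiation hazard (fitted on
   the un-cloned person-days at risk) supplies per-clone-day probabilities of
   remaining uncensored; weights are cumulative products of their reciprocals.
4. The IPC-weighted discrete-time Aalen–Johansen estimator gives each
   regime's cumulative incidence of ICU death and discharge; variance by
   patient-level infinitesimal jackknife or bootstrap; expected RRT
   initiations by the same estimator with initiation as the event.
5. The mortality-minimising regime is selected; overoptimism is quantified
   with a k-fold cross-validation benchmark (weights refit per fold).

Because real ICU data of this kind are access-restricted, the synthetic
generator provides a stand-in with the essential confounding structure:
time-varying labs drive both treatment decisions and the competing hazards,
and dialysis is harmful when started without an absolute indication but
beneficial when indicated, so an interior regime of the grid is optimal. The
oracle simulates the same mechanism with initiation forced to follow a given
regime, giving ground truth to validate the whole pipeline against.
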