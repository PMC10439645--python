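# causaltransport

Will a clinical prediction model still be trustworthy in a hospital whose
patients look different from the development cohort?  `causaltransport` is a
simulation laboratory for that question, built around a concrete task:
predicting cognitive impairment from demographic, genetic, biomarker, and
imaging-derived variables in an elderly memory-clinic population.

The package lets you

1. describe the variables and their direct causal relations as a **DAG**
   (plain-text edge list; d-separation queries, implied conditional
   independencies, and partial-correlation tests of them against data);
2. quantify the DAG with **structural equations** — one linear-Gaussian
   equation per continuous node, one latent-threshold (probit) equation per
   binary node — estimated from a cohort table or loaded from a parameter
   file;
3. generate **semi-synthetic cohorts** by bootstrapping the exogenous
   variables (age, APOE ε4 carriage, sex) and forward-simulating everything
   else, and simulate *external settings* by guided interventions: replacing
   an exogenous distribution (mean age 73.9 → 35 or 65), setting a prevalence
   (APOE ε4 46.9% → 5%), or rewriting a structural mechanism (the CSF-tau
   equation);
4. train **logistic, lasso, random-forest, and gradient-boosting** classifiers
   on four predictor schemes derived from the graph — all variables, parents
   (direct causes) of the outcome, children (consequences) of the outcome, or
   exogenous variables only;
5. measure **transportability** as internal-minus-external differences of the
   integrated calibration index (ICI), the bias-corrected reliability
   component of the Brier decomposition, and the AUC, aggregated as
   median [2.5%, 97.5%] over repeated simulation.

The phenomenon the pipeline exposes: models that predict with *causes* of the
outcome keep their calibration under interventions, while *anti-causal*
models (predicting from consequences, e.g. brain volumes or cognitive test
scores) can miscalibrate badly even when their AUC barely moves.

## Core quantities

For predicted risks `p̂ᵢ` and outcomes `yᵢ ∈ {0,1}`:

* **ICI** = mean |p̂ᵢ − f(p̂ᵢ)| where `f` is a local-linear (tricube, span
  0.75) smooth of `y` on `p̂` — the average absolute distance between the
  calibration curve and the diagonal.
* **Brier decomposition** over decile bins of `p̂`: REL − RES + UNC = Brier
  (binned), with the small-sample bias corrections applied to each component;
  reliability (REL) is the calibration term reported.
* **AUC** via the Mann–Whitney statistic (concordant + ½·tied pairs).
* **Transport delta** = internal − external per repetition: negative
  calibration deltas and positive AUC deltas both mean degraded external
  performance.

## Worked example

Train logistic models on causal (parents) and anti-causal (children)
predictor schemes, then compare calibration across the four intervention
settings (50 repetitions, cohorts of 10,000):

```python
from causaltransport import fixtures as fx
from causaltransport.pipeline import ExperimentConfig, run_experiment

cfg = ExperimentConfig(
    graph=fx.canonical_dag(),
    params=fx.default_parameter_set(),
    exogenous=fx.default_exogenous_source(),
    settings=fx.standard_interventions(),
    n=10_000, repetitions=50, master_seed=1,
    algorithms=["logistic"], schemes=["parents", "children"],
)
bundle = run_experiment(cfg)
s = bundle.transport_summary
print(s[s.metric == "delta_ici"].round(4).to_string(index=False))
```

```
algorithm   scheme setting    metric  median    p2_5   p97_5  n_reps
 logistic  parents     age delta_ici -0.0073 -0.0322  0.0048      50
 logistic  parents    age2 delta_ici -0.0007 -0.0072  0.0065      50
 logistic  parents   apoe4 delta_ici -0.0019 -0.0095  0.0039      50
 logistic  parents     tau delta_ici  0.0007 -0.0026  0.0065      50
 logistic children     age delta_ici -0.1085 -0.1224 -0.0965      50
 logistic children    age2 delta_ici -0.0248 -0.0340 -0.0153      50
 logistic children   apoe4 delta_ici -0.0558 -0.0684 -0.0449      50
 logistic children     tau delta_ici -0.0957 -0.1050 -0.0895      50
```

Parents-scheme deltas sit within a few thousandths of zero in every external
setting: the causal model's calibration transports.  The children-scheme
model loses 0.02–0.11 ICI (negative delta = worse calibration externally),
most severely under the age shift and the tau-mechanism change — the
anti-causal mapping from consequences back to the outcome is exactly what
those interventions disturb.

A command-line interface wraps the same machinery:

```sh
causaltransport fixtures out/           # emit fig1.dag, params_default.json, adni_like.csv
causaltransport fit-sem out/adni_like.csv out/fig1.dag -o out/fitted.json
causaltransport run config.yaml         # full repeated experiment from YAML
causaltransport report results/         # summary tables + density plots
```

## Layout

| module | contents |
| --- | --- |
| `causaltransport.graph` | DAG parsing/serialization, d-separation, implied independencies, CI tests |
| `causaltransport.sem` | z-normalization, per-equation estimation, parameter files |
| `causaltransport.generate` | exogenous sampling, interventions, forward simulation |
| `causaltransport.models` | the four classifier families over predictor schemes |
| `causaltransport.metrics` | ICI, Brier decomposition, AUC, deltas, percentile summaries |
| `causaltransport.pipeline` | repeated-experiment engine, reporting, resume |
| `causaltransport.fixtures` | canonical 17-node DAG, default parameters, baseline cohort generator |

See `docs/methods.md` for the model, its assumptions, and the numerical
choices.
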