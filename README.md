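# tbipred

Risk modelling for **moderate-to-severe pediatric traumatic brain injury
(TBI)** in an emergency-department population with a very low event rate.
The package re-implements, as a tested and reusable pipeline, a
case–control analysis in which two competing prediction models are
derived from history and physical-examination findings and compared by
ROC analysis:

1. **Multivariable logistic regression** with a two-step variable
   selection — a univariable screen at *p* < 0.2 followed by stepwise
   selection (entry *p* = 0.1, removal *p* = 0.05) — reporting adjusted
   odds ratios with Wald 95% CIs and AIC/BIC/log-likelihood.
2. **An under-sampling ensemble of extreme learning machines (ELM).**
   Given the minority (case) set *P* and majority (control) set *N*, each
   of *T* = 100 base classifiers trains on a balanced subset
   *P* ∪ *N<sub>t</sub>* with |*N<sub>t</sub>*| = |*P*|, drawn uniformly
   without replacement. Each base classifier is a single-hidden-layer
   feed-forward network (30 hidden neurons, sigmoid activation) whose
   hidden layer is random and fixed, and whose output weights are the
   least-squares solution (the ELM training rule). The hard votes
   φ<sub>t</sub>(x) ∈ {0, 1} combine into a risk score

   RS<sub>x</sub> = 100 · Σ<sub>t=1..T</sub> φ<sub>t</sub>(x, L<sub>t</sub>) / T,

   an integer-granular score on [0, 100].

Both scores are evaluated by ROC curves, AUC, and — at the cutoff nearest
the (0, 1) corner of ROC space — sensitivity, specificity, PPV and NPV
with 95% CIs.

Patient-level data from the source registry are not public, so the
package ships a **synthetic case–control generator** calibrated to the
published marginal summaries (39 cases with 156 age-matched controls at a
4:1 ratio, year-for-year matching, ages ≈ Normal(8.1, 4.2) truncated to
[0, 16), class-conditional Bernoulli predictors at the published
prevalences), plus the published univariable contingency tables embedded
as fixtures. It is aimed at biostatisticians and methods researchers who
want a reproducible testbed for imbalanced-class clinical risk scores.

## Worked example

```python
from tbipred.pipeline import RunConfig, run_study

bundle = run_study(RunConfig(n_cases=39, seed=7))

print(bundle["univariable"].loc[["loc", "vomiting", "seizure"],
                                ["case_yes", "control_yes", "p", "method"]])
for row in bundle["odds_ratios"]:
    print(f"{row.predictor:22s} OR {row.odds_ratio:6.2f} "
          f"[{row.ci_low:.2f}-{row.ci_high:.2f}]  p={row.p:.3f}")
c = bundle["comparison"]["metrics"]
print(f"AUC   ML {c['auc']['ml']:.3f}   LR {c['auc']['logistic']:.3f}")
```

Output:

```text
          case_yes  control_yes             p  method
variable
loc             27            8  5.453024e-17  fisher
vomiting        11           20  2.685448e-02  fisher
seizure          5            0  2.580431e-04  fisher
rta                    OR 143.86  [14.99-1380.36]  p=0.000
loc                    OR  18.79  [4.80-73.54]  p=0.000
vomiting               OR   3.60  [0.85-15.35]  p=0.083
bos_fracture_signs     OR  27.27  [3.33-223.56]  p=0.002
AUC   ML 1.000   LR 0.915
```

The univariable table is the case/control cross-tabulation of each
predictor on this synthetic draw (27 of 39 cases vs 8 of 156 controls
with loss of consciousness, Fisher *p* ≈ 5e-17). The odds-ratio table is
the 4-variable multivariable logistic fit — the wide intervals are
typical for 39 cases. The final line compares apparent AUCs: the
7-variable ELM ensemble separates this cohort perfectly (1.000) while
the 4-variable logistic model reaches 0.915.

The same pipeline is available from a shell:

```sh
tbipred simulate --seed 7 --out cohort.csv
tbipred analyze cohort.csv
tbipred run-all --seed 7 --outdir run7/
```

`run-all` writes the cohort CSV, univariable report, both fitted models,
ROC points, per-class score histograms, performance reports and the
model comparison; identical config + seed reproduces the bundle exactly.

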