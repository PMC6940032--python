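# irtqol

Multidimensional item response theory (IRT) for ordinal health
questionnaires: a reusable pipeline for the psychometric evaluation of
patient-reported outcome scales such as the SF-36 Health Survey, the
EQ-5D, and the Hospital Anxiety and Depression Scale (HADS).

Instruments like these are scored in the clinic as sums and index values,
but the quantities they try to measure — health-related quality of life,
emotional distress — are latent traits. Whether a questionnaire measures
its trait well in a *given population* is an empirical question, and
answering it requires fitting latent-variable measurement models and
interrogating their fit. `irtqol` implements that workflow end to end for
researchers in biostatistics and outcomes measurement:

* **Functional model.** The logistic graded response model (GRM) in
  slope–intercept form: for item *j* with ordered categories
  *k* = 0…K−1 and latent trait vector **θ**,

  P\*(x<sub>j</sub> ≥ k | **θ**) = 1 / (1 + exp(−(**a**<sub>j</sub>·**θ** + d<sub>jk</sub>))),

  with strictly decreasing intercepts d<sub>j1</sub> > … > d<sub>j,K−1</sub>
  and category probabilities as differences of adjacent cumulative
  probabilities. K = 2 reproduces the two-parameter logistic model exactly.
* **Structural models.** Unidimensional, correlated-traits, bifactor, and
  two-tier confirmatory structures (named candidate sets per instrument are
  shipped), with optional oblique general factors and a positive-loadings
  constraint.
* **Estimation.** Full-information marginal maximum likelihood by
  Bock–Aitkin EM on a fixed quadrature grid, with two-tier dimension
  reduction (generals + one specific cluster at a time), so every shipped
  structure needs at most 3 integral dimensions. Missing responses are
  skipped under MAR; monotone convergence is recorded per fit.
* **Model selection and fit.** AIC/BIC; the limited-information M2
  statistic on univariate+bivariate margins with RMSEA (90% CI), SRMSR,
  TLI, CFI; residual correlations; rest-score S-X2 item fit;
  observed-vs-expected category tables; Zh person fit.
* **Scoring.** EAP and MAP trait estimates with posterior standard errors,
  empirical reliability var(θ̂)/(var(θ̂)+mean SE²), standardized loadings
  λ = (a/1.702)/√(1+Σ(a/1.702)²), and explained common variance (ECV).
* **Stability.** The 5-fold cross-validation protocol: frozen-parameter
  validation fit, validation refit, and parameter/score deltas.
* **Comparators.** Conventional scores from editable config tables: HADS
  subscale sums, SF-36 subscales and component summaries, and the EQ-5D
  UK time-trade-off utility index.
* **Synthetic data.** Generator presets that emulate the three
  instruments' response structure (category counts, latent structures,
  missingness rates at registry scale), so the full pipeline is testable
  without access to any patient data.

## Worked example

```python
import irtqol as q

spec  = q.preset("eq5d", n_persons=2000, seed=1)   # 5 items, K=3, 1 factor
data  = q.simulate(spec)                           # ordinal matrix + 2.1% MCAR
model = q.fit_em(data, spec.structure, seed=1)
rep   = q.fit_report(data, model)
print(rep.rmsea, rep.srmsr, rep.tli, rep.cfi)
```

Running `examples/01_simulate_and_fit.py` prints (abridged):

```
simulated 2000 persons x 5 items, 2.0% missing cells
EM converged=True after 13 iterations, marginal loglik = -7587.1

item   true a  est a   true d            est d
eq1     1.30   1.11   [ 1.9  -1.62]     [ 1.85 -1.51]
eq2     1.70   1.71   [-0.88 -1.28]     [-0.85 -1.27]
...
```

The estimated slopes (discriminations) and intercepts recover the
generating values to within sampling error at N = 2000. The fit-assessment
example on the same design prints `RMSEA = 0.015 (90% CI 0.000-0.024)`,
`SRMSR = 0.015`, `TLI = 0.976, CFI = 0.979` — all inside the conventional
acceptability thresholds (≤ 0.05, ≤ 0.05, ≥ 0.90), as they should be when
the fitted family contains the generating model. The scoring example on
the HADS-like bifactor preset reports an empirical reliability of 0.85
for the general emotional-distress factor with ECV 0.79: a strong but not
strictly unidimensional general trait.

Each script in `examples/` is a short narrative: it builds or loads a
small input, runs one capability, and explains the numbers it prints.
A thin command-line pipeline (`irtqol simulate|fit|compare|crossvalidate|
score|report`) wraps the same functions and writes CSV artifacts plus a
JSON run manifest per step.

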