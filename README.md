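# flowtoj

Analysis pipeline for a psychophysics question: **does being "in flow" change
what you perceive?** Athletes and musicians report that time slows down and
perception sharpens during absorbed, high-performance states. `flowtoj`
implements the complete measurement-and-inference chain used to test that
claim with a temporal order judgement (TOJ) task administered before and
after real sport/music sessions, together with a generative simulator of the
whole study, so every estimator in the chain can be validated by parameter
recovery.

It is written for psychophysicists and behavioural statisticians who want a
tested, scriptable implementation of:

* **1-up-3-down adaptive staircases** controlling the stimulus onset
  asynchrony (SOA) of a left/right TOJ (start 267 ms, step 16.7 ms, 14
  reversals; the rule converges where P(correct) = 0.5^(1/3) ≈ 0.794);
* **logistic psychometric fits** per cue grouping,
  P(right first) = Λ(β₀ + β₁·SOA), with the closed-form estimates
  **JND = ln 3 / β₁** (temporal resolution) and **PSS = −β₀/β₁** (point of
  subjective simultaneity; its dependence on exogenous/endogenous cue side
  indexes prior entry — attended stimuli are perceived earlier);
* **AFSS flow scoring**: 26 Likert items, nine subscales, global score =
  item mean, Cronbach's α;
* **robust screening**: exclusion beyond 2.5 scaled median absolute
  deviations (b = 1.4826) around the median, applied to pooled JNDs and to
  pooled post-minus-pre PSS-distance differences;
* **hierarchical moderation models**: a three-level Gaussian mixed model for
  the JND (measurements in sessions in subjects) and a two-level model with
  a per-subject random condition slope for the left/right cued PSS distance,

  `value ~ condition + flow_c + prepost + prepost:flow_c`,

  where the `prepost × flow` coefficient is the quantity of interest: ms of
  pre-to-post perceptual change per unit of session flow. Frequentist fits
  (REML/ML, Wald CIs, likelihood-ratio tests, variance partition) are
  mirrored by a conjugate-Gibbs Bayesian counterpart with split-R̂
  diagnostics and PSIS-LOO model comparison.

## Worked example

```python
from flowtoj import PipelineConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(mode="simulate", seed=1), "out/")
print(bundle["models"]["jnd"].summary())
```

prints (this exact output for seed 1):

```
Flow moderation model (JND response), REML

Predictor               Estimate   Std.Err   CI 2.5%  CI 97.5%       t        P
Intercept                  58.95      3.57     51.95     65.96   16.50 3.53e-44
condition                  13.95      2.33      9.38     18.52    5.98 6.13e-09
flow_c                      0.58      2.39     -4.11      5.28    0.24    0.808
prepost                    -2.38      2.33     -6.95      2.19   -1.02    0.309
prepost:flow_c             -5.13      3.04    -11.09      0.83   -1.69   0.0924

Random effects (variances, ms^2):
  Var: subject                    227.52
  Var: session:subject             20.90
  sigma2                          419.82
Num. obs. 311
Num. groups: subject 27
Num. groups: session:subject 81
```

Reading it: the average pre-performance JND is ~59 ms; exogenous cueing
inflates measured JNDs by ~14 ms; and each extra unit of reported flow is
associated with a ~5 ms *additional improvement* (negative sign) of the JND
from pre- to post-performance — the simulated ground truth for this
moderation is −5.8 ms per flow unit. The same bundle contains the PSS model,
the screening report (`bundle["screening_report"]`), flow scores, and every
intermediate table written as CSV under `out/`.

The same chain is available from the shell:

```bash
flowtoj simulate --seed 1 --outdir out
flowtoj estimate --trials out/trials.csv --out out/estimates.csv
flowtoj screen   --estimates out/estimates.csv --out out/screened.csv
flowtoj score    --questionnaire out/questionnaire.csv --out out/flow.csv
flowtoj model    --estimates out/screened.csv --flow-scores out/flow.csv --outdir out
```

`flowtoj reproduce` runs the estimation half of the chain on externally
collected per-trial CSV tables (with a configurable column mapping).

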