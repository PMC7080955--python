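# Methods

This note documents the generative model, the estimators, the numerical
choices, and the known limitations of `flowtoj`.

## The observer and the staircase

A TOJ observer reports which of two lateralised targets appeared first. Its
response law is a lapse-contaminated logistic in the signed SOA
(positive ⇔ right target first; "right-first" responses coded 1):

    P(right first) = λ/2 + (1 − λ) Λ((SOA_signed − μ_cue) / s)

with logistic scale `s` (ms), lapse rate `λ ∈ [0, 0.1]`, and a prior-entry
displacement `μ_cue = ∓shift_c` for a right/left cue of type
`c ∈ {endogenous, exogenous}`. The implied just noticeable difference is
`JND = s·ln 3` (half the 25%→75% span). Shifts may be negative — session
noise can put the measured cued advantage on the "wrong" side — so the shift
fields are constrained to be finite, not non-negative; the sign carries the
direction of prior entry.

The staircase starts at 267 ms (16 frames of a 60 Hz display; the
frame-grid check allows 0.05-frame slack for conventionally rounded
values), moves down one 16.7 ms step after three consecutive correct
responses and up one step after each error, and terminates at the 14th
reversal (the terminating trial is kept). Choices where the procedure
itself is silent:

* **SOA floor = one frame (16.7 ms)**, not 0: at SOA 0 "correct" is
  undefined and a 60 Hz display cannot show a smaller asynchrony. A 500 ms
  cap prevents unbounded walks for guessing observers.
* **Reversals are counted on applied moves**; an intended move fully
  absorbed by the floor/cap clamp is a non-move and neither changes the
  direction history nor counts as a reversal.
* A block that fails to terminate within 10⁴ trials aborts with a
  diagnostic (this requires a pathological observer, e.g. one that is never
  wrong).

The 1-up-3-down rule has its fixed point where P(correct) = 0.5^(1/3) ≈
0.794. Two regimes must not be conflated when checking this: the descent
from 267 ms is a near-ceiling transient that occupies a large share of a
14-reversal block (trial-weighted accuracy over whole blocks is ≈ 0.83).
The package's convergence check therefore measures accuracy over the
asymptotic regime — trials after the 7th reversal — which sits within 0.02
of the fixed point; this burn-in convention is the standard one for
staircase threshold estimates.

## Psychometric estimation

Each grouping of trials (per participant × session × phase × condition:
one pooled-cue fit for the JND, one fit per cue side for the PSS) is fitted
by per-trial Bernoulli maximum likelihood under
`P = Λ(β₀ + β₁·SOA)`, using Newton steps with step-halving, convergence
when the relative log-likelihood change is below 1e-10 (max 100
iterations). No lapse or guess asymptote is fitted: the observer's lapse
and the cue-side pooling then attenuate the fitted slope exactly as they do
in plain logistic analyses of real TOJ data; this misspecification is
intended realism, not a defect.

Degenerate groupings (fewer than two SOA levels, one response class,
complete or quasi-separation, singular information) return a non-converged
fit with a reason instead of raising, so whole-study estimation never
aborts. Closed forms from a converged fit: `JND = ln 3/β₁`,
`PSS = −β₀/β₁`; `PSS_distance = PSS(left-cued) − PSS(right-cued)`
(positive = prior entry toward the cued side). Negative-slope fits yield
estimates flagged for screening rather than dropped. A complete participant
contributes 12 JND and 24 PSS models over three sessions.

## Flow scoring

The 26 AFSS items (5-point Likert) are averaged into the global flow score;
subscale means use consecutive item blocks of sizes (3,3,4,2,3,3,2,3,3) —
the published item→subscale assignment is not reproduced in the source
material, so the mapping is configurable. Cronbach's α uses sample (n−1)
variances throughout; the alternative (n) convention shifts α slightly, so
the choice is stated. No reverse-scored items are assumed.

## Robust screening

Values with `|x − median| > k·b·MAD` are excluded, `k = 2.5`, consistency
constant `b = 1.4826` (so the threshold is ≈ 2.5 SD for Gaussian data,
excluding ≈ 1.24%). JNDs are screened pooled across the whole study;
PSS-distance screening operates on pooled post-minus-pre differences per
(participant, session, condition), and an excluded difference removes both
its pre and post rows. Unpaired runs (one phase missing) cannot form a
difference and are left unscreened. Non-converged estimates enter the JND
pool as missing values and are always excluded. If the MAD is zero the rule
is degenerate and excludes nothing (with a warning).

A consequence worth knowing: screening on the post-minus-pre *outcome*
difference is selection on the response variable, which attenuates the
flow-moderation coefficient that same difference carries (measured ≈ 3% for
the JND and ≈ 10% for the PSS model at the default study conditions). The
recovery tests quantify this by running both the screened and the
unscreened pipeline; the unscreened estimator is unbiased.

## The study generator

`generate_study` emulates the field design: 27 participants (11 athletes,
16 musicians) × 3 sessions × {pre, post} × {endogenous, exogenous}
staircase blocks, a 26-item questionnaire per session, and dropout. Latent
truth per participant i, session s, condition c, phase p:

    JND_iscp  = μ + u_i + v_is + b_c·c + p·(δ + γ_JND·f̃_is) + e_iscp
    dist_iscp = μ' + w_i + (b'_c + slope_i)·c + p·(δ' + γ_PSS·f̃_is) + e'_iscp

with `u_i ~ N(0, 331.62)`, `v_is ~ N(0, 152.93)`, `e ~ N(0, 343.18·κ^p)`
(ms²; κ defaults to 1) for the JND, and subject intercept/condition-slope
covariance (153.05, 1427.08, cov 373.90) with σ² = 2053.72 for the PSS
distance; grand means and fixed offsets default to μ = 53.3, b = 10.42,
δ = −5.36, γ_JND = −5.8 and μ' = 41.12, b' = 64.12, δ' = 6.84,
γ_PSS = −21.31. Every observation carries its own residual (pre and post
alike), making the planted coefficients exactly the estimands of the fitted
models.

`f̃_is` is the grand-mean-centred **reported** global flow score of the
session: latent flow is drawn from a truncated normal (mean 3.43, SD 0.7 on
the 1–5 scale; the SD is chosen so ~80 session scores plausibly span the
observed 1.6–4.9 range), items are
`clip(round(latent + N(0, 0.7²)), 1, 5)`, and the moderation acts on the
item mean. Planting γ on the latent flow instead would dilute the fitted
interaction by item measurement error (~15%) — the regression coefficient
the models estimate is defined on the measured score, so that is where the
truth is planted.

Each block's observer is derived from the latent truth:
`s = JND/ln 3` (residual draws implying a non-positive scale are resampled
and logged, never clamped) and `shift_c = dist/2`, since the left/right
cued PSS distance of a symmetric observer equals twice its shift. Default
lapse 0.02. Dropout deletes each (participant, session, phase) run — one
pre or post block-pair — independently with probability 5/162, reproducing
an expectation of five missing runs; the questionnaire is always retained.
The RNG is forked per participant, so dropping or reordering participants
leaves everyone else's data bit-identical.

What the generator does **not** emulate: learning or fatigue across
sessions or within blocks, response-time structure, serial dependence of
responses, item-level questionnaire structure beyond a single latent
factor, and real participants' error bursts (which drive the ~12%
exclusion rates seen with human data; clean synthetic data loses ~1–3%).
Passing recovery tests therefore validate the estimators under the stated
model, not the behavioural realism of human TOJ data.

### Full-chain bias

Running the complete chain (staircase → logistic fits → models) inflates
JND-scale quantities multiplicatively: pooling left- and right-cued trials
mixes two curves displaced by ±shift, flattening the pooled slope, and the
lapse adds further attenuation. Because the displacement itself depends on
flow (through γ_PSS), the flattening is flow-dependent and the fitted JND
moderation over-shoots (≈ −7.7 vs −5.8 ms per flow unit at the default
conditions). This is a property of the measurement model shared with real
TOJ analyses of this design, documented here and covered by a qualitative
test; quantitative recovery is asserted at the estimate level, where the
estimator is unbiased.

## Hierarchical models

JND model: three levels — random intercepts for subjects and for sessions
nested in subjects (`vc_formula`-style dummy variance component). PSS
model: two levels — per-subject random intercept and random condition
slope with free covariance (the unconditional PSS variance partition uses
the intercept-only random structure). Fixed effects default to
`condition + flow_c + prepost + prepost:flow_c`; `domain`,
`prepost:domain`, and three-way flow interactions with condition or the
control question are available as optional terms. Coding: prepost 0 = pre /
1 = post; condition 0 = endogenous / 1 = exogenous; domain 0 = musician /
1 = athlete; flow grand-mean-centred (raw coding is runnable; centring
moves the intercept, never the interaction).

Estimation is REML for reported coefficients and ML for likelihood-ratio
comparisons (statistic 2Δll, df = parameter-count difference; nested terms
and identical rows enforced). Optimisation tries lbfgs, then bfgs, then
Powell, keeping the first converged fit; singular fits (a variance
component at ~0) are flagged, not hidden. Inference conventions: Wald 95%
CIs (± 1.96 SE) and t statistics on `n_obs − rank(X)` residual degrees of
freedom — no Satterthwaite/Kenward–Roger correction, so small-sample
p-values are mildly liberal; the null-calibration test shows the
interaction test's type-I error is ≈ 5% at the default design. Rows lacking
a flow score or a finite estimate are dropped listwise.

## Bayesian counterpart

The same linear predictors and random structures are sampled by a blocked
Gibbs sampler with conjugate priors: N(0, 10⁶) on each fixed effect,
Inverse-Gamma(10⁻³, 10⁻³) on scalar variances, and
Inverse-Wishart(ν₀ = 4, I) on the 2×2 PSS random-effect covariance. These
weakly-informative conjugate priors give exact full-conditional updates;
at the data scale of this design (variances of 10²–10³ ms²) they are
practically flat. Four chains by default; split-R̂ (arviz) above 1.01 on
any fixed effect marks the run non-usable. Model comparison ("does the
interaction improve prediction?") uses PSIS-LOO on the pointwise
log-likelihood conditional on the sampled random effects, with the SE of
the elpd difference from the pointwise contributions. The intercept mixes
slowest (it trades off against the random-intercept mean); 400+ warmup and
1000+ retained draws per chain keep R̂ below the threshold in the shipped
configurations.

## Problem sizes

The test suite and the acceptance script use sizes chosen to give stable
Monte-Carlo statements at desk scale: 1000 staircase blocks for the
fixed-point check; 200 replicate studies (27 × 3, estimate-level) for
moderation recovery, with screened and unscreened variants; 500 replicates
for null calibration and p-value uniformity; 10⁴ draws for the Gaussian
MAD rate; 60 replicates and 200 null replicates in the acceptance script.

## Known limitations

* The reproduction path (`flowtoj reproduce`) expects external per-trial
  CSVs and a column map; it has been exercised on synthetic tables shaped
  like a deposit, not on human data shipped with the package.
* Degrees-of-freedom and CI conventions are deliberately simple (Wald,
  residual df); exact small-sample inference is out of scope.
* No probit/Weibull links, no lapse-parameter psychometric fits, no
  QUEST/Psi adaptive procedures, no generalized (non-Gaussian) mixed
  models, no cross-classified random structures.
* MAD screening scope (pooled vs per-group) is configurable only through
  the code path that calls `mad_mask`; the shipped pipeline implements the
  pooled reading described above.
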