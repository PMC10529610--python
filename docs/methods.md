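# Methods

## Perceptual models

The binary HGF tracks a hierarchy of hidden states: the binary outcome
x₁, its tendency x₂ in logit units, the log-volatility x₃ of x₂, and —
in the 4-level variant — the log-volatility x₄ of x₃. Each level i ≥ 2
evolves as a Gaussian random walk whose step variance is
exp(κᵢ·x_{i+1} + ωᵢ), with the top level stepping with fixed variance
ϑ > 0 (also exposed in log space as the top-level ω, so every level's
volatility is reported on the same scale). Filtering uses the standard
variational one-step updates for binary inputs: the first-level
prediction is μ̂₁⁽ᵏ⁾ = s(μ₂⁽ᵏ⁻¹⁾) with s the logistic; the level-2
posterior moves by the outcome prediction error δ₁ weighted by the
ratio of prediction precisions; levels 3 and 4 move by
precision-weighted volatility prediction errors. The implementation is
guarded by an independently hand-transcribed one-step oracle in the
test suite (agreement to 1e-10), and the clamping identity — HGF4 with
κ₃ = 0 and the level-3 step variance matched to ϑ reproduces HGF3
exactly — is tested at the same tolerance.

Couplings κᵢ default to 1 and are fixed during fitting, the standard
binary-HGF convention; the estimable surface is ω₂ (and ω₃ for HGF4),
ϑ, and the response parameter ζ. Initial beliefs are μ₂⁽⁰⁾ = 0 (maximal
uncertainty about the contingency), μ₃⁽⁰⁾ = μ₄⁽⁰⁾ = 1, with variances
(0.1, 1, 1). A filter trajectory whose posterior precision turns
non-positive (possible at levels ≥ 3 for extreme parameters) raises a
divergence error carrying the trial index; the inverter converts this
into a large finite penalty so the optimiser retreats.

The associative alternatives are Rescorla–Wagner
(v ← v + α(u − v), α fixed) and Sutton's K1 rule, a scalar IDBD scheme:
the log learning rate accumulates μ_meta·δ⁽ᵏ⁾·h⁽ᵏ⁻¹⁾ where h is a
decaying eligibility trace of recent updates, and α is bounded to
(0, 1]. With μ_meta = 0 the K1 state sequence equals Rescorla–Wagner
bit for bit (the log rate is stored as an increment relative to
log α₀ to make the reduction exact in floating point).

**Per-trial learning rates.** The paper-facing quantities α₂ and α₃ are
operationalised as update/prediction-error ratios: α₂⁽ᵏ⁾ is the fraction
of δ₁ absorbed into the first-level prediction,
(s(μ₂⁽ᵏ⁾) − μ̂₁⁽ᵏ⁾)/δ₁⁽ᵏ⁾, and α₃⁽ᵏ⁾ the analogous ratio for δ₂.
Subject summaries are means over valid trials within condition; trials
with δ ≈ 0 are skipped. Trajectory summaries for μ₂ and μ₃ are
within-condition means (final values are also exportable).

## Response model

A single inverse decision temperature ζ > 0 shapes the unit-square
sigmoid p(y=1) = b^ζ / (b^ζ + (1−b)^ζ), computed stably as
expit(ζ·logit(b)). The belief b driving trial k's response is the
*previous* trial's posterior (μ̂₁⁽ᵏ⁾ for the HGFs, v⁽ᵏ⁻¹⁾ for the
associative models), making ζ = 1 probability matching and large ζ a
step function at b = 0.5. The Bernoulli likelihood clamps probabilities
at 1e-12 so a deterministic miss is finitely penalised.

## Inversion

Fitting is MAP estimation in transformed space — log for positive
parameters (ϑ, ζ, μ_meta), logit for unit-interval parameters (α, v₀),
identity for the ωs — with independent Gaussian priors of variance 4
("relatively uninformative"; roughly ±4 logit units or e^±4-fold). The
HGF4 top-level variance is pinned by a tight prior (variance 1e-4):
short binary series carry essentially no information about the
volatility of volatility, and pinning reproduces the expected
degeneracy without hard-coding it. Optimisation is L-BFGS-B from 10
jittered restarts (jitter SD = half the prior SD; the first start is
the prior mean), gradient tolerance 1e-6.

Model evidence uses the Laplace approximation
LME = log p(y, θ_MAP) + (d/2)·log 2π − ½·log det H, with H the central
finite-difference Hessian (relative step 1e-4, symmetrised). Indefinite
Hessians are repaired by flooring eigenvalues at 1e-8 and flagged; an
irreparable Hessian falls back to a flagged BIC value. On an exactly
quadratic 1-parameter log-joint the approximation equals the Gaussian
integral (tested to 1e-8), and it is invariant under affine
reparameterisation with a consistently transformed prior.

**Prior elicitation.** An ideal-observer procedure is provided: prior
means minimise the mean Bernoulli surprise of a model's own
one-step-ahead predictions over the design input sequences, searched in
a box of ±6 transformed units around the defaults. On sequences with a
near-stationary contingency this surface is monotone (the least
surprised agent barely learns) and the minimiser sits on the box
boundary; such corner solutions signal that elicitation is
uninformative, so the synthetic studies fit with the documented default
priors instead. Elicitation remains available (`RunConfig.elicit`) for
structured sequences, where it finds interior optima.

**Recovery harnesses.** `parameter_recovery` draws dispersed true
parameters, simulates agents, refits them, and reports true-recovered
correlations, bias, RMSE and the identifiability matrix (pairwise
correlations among recovered parameters). On 320-trial series
Rescorla–Wagner's α recovers with r ≥ 0.8 and |α̂ − α| ≤ 0.1; on
task-length series (45–90 trials) HGF3's ω₂ recovers with r ≥ 0.5.
`model_recovery` runs the full simulate-fit-select loop per generating
model and returns the confusion matrix of PXP winners.

## Model selection

Random-effects BMS treats the model identity as a subject-level random
variable with unknown population frequencies r ~ Dirichlet(α₀ = 1).
A variational scheme alternates subject responsibilities (softmax of
LME plus digamma terms) with Dirichlet updates to convergence (1e-6).
Exceedance probabilities come from 1e5 Monte-Carlo Dirichlet draws,
replaced by the exact Beta comparison for K = 2 and by exact uniformity
for a symmetric posterior. The Bayes omnibus risk compares the
variational free energy of the random-effects model against the null
of equal frequencies; PXP_k = EP_k·(1−BOR) + BOR/K.

Family-level inference aggregates each family's evidence per subject
under a uniform within-family prior, L_fam = logsumexp(members) − log m,
and runs the same scheme over families. This matters here: 32-trial
binary series cannot separate the two HGF depths (their LMEs are nearly
identical), and a model-level BMS dilutes the hierarchical evidence
across the two variants, inflating BOR. The headline protected
exceedance probability is therefore reported for the
hierarchical-vs-associative family partition.

## Group statistics

Student's or Welch's t (selectable; a variance-ratio screen at 4:1
triggers Welch automatically) with pooled-SD Cohen's d; a 2 × 2 mixed
ANOVA (pingouin's partitioning; with one between and one balanced
within factor the sums-of-squares types coincide, verified against an
explicit hand partitioning) with η_p² = SS_effect/(SS_effect+SS_error);
Friedman (own tie-corrected implementation — the 2-condition case the
analysis needs is refused by scipy; cross-checked against scipy for
k = 3), Kruskal–Wallis and Mann–Whitney with a tie-corrected normal
z and rank-biserial effect size; and step-down Holm–Bonferroni
(cross-checked against statsmodels). Sensitivity power uses the
noncentral t (exact two-tailed power, inverted by Brent's method) and
noncentral F for the mixed-design interaction. The interaction
noncentrality convention defaults to λ = f²·N (the effect size is taken
as already incorporating the repeated-measures correlation, as SPSS
reports it); the G*Power convention λ = f²·N·m/(1−ρ) is available with
a configurable ρ (default 0.5).

## Synthetic data: what it does and does not emulate

Designs reproduce the tasks' trial grammar exactly: 5 baseline +
32 test lifts with 8 per object and the heavy-before-light constraint
(three fixed pseudorandom orders are shipped, generated once under the
constraint as synthetic stand-ins for the unpublished originals);
45-trial interception conditions with exactly 30 expected /
15 unexpected trials, volatile block lengths from {6, 9, 12} at
contingencies {0.83, 0.67, 0.50} with per-block counts constrained to
the exact totals. The stable condition's marginal probability is the
exact count ratio 30/45.

Agents sample binary responses from the fitted model family, so
simulated cohorts share the generative structure the pipeline assumes —
passing tests demonstrate internal consistency (coding, fitting,
selection and statistics recover planted structure), not that real
grip-force or gaze data obey these models. Raw traces use simple
parametric kinematics: a logistic force rise (amplitude linear in the
heaviness belief; peak rate A·r/4 in closed form) and a
pursuit-then-fixation gaze profile (fixation pitch equal to the
belief-driven target). They exercise the preprocessing operators with
known ground truth but are not biomechanically or oculomotorically
faithful; interception success, ball flight and rendering are out of
scope.

Study conditions, fixed once: the SWI model-comparison cohort draws
ω₂ ~ U(−3.5, −2), ω₃ ~ U(−7, −5), ϑ = 0.0025 and ζ log-uniform on
[10, 30] — beliefs held with enough decision consistency that the
trial-level likelihood is informative, while responses remain
stochastic. The planted interception cohort fixes ζ = 8 and
ϑ = 0.0025 for both groups; the neurotypical-like group's ω₂ rises
from −3.5 (stable) to −2.0 (volatile) while the autism-like group
holds −3.0 in both conditions — a condition-sensitivity difference,
not a blanket group offset.

## Preprocessing choices

Grip force: 2nd-order 14 Hz Butterworth applied forward-backward
(zero phase; the order is a package choice, matching the stated
2nd-order gaze filter), then a 5-point central difference (exact
through degree-4 polynomials); the peak is taken over the supplied
pre-contact window (whole trace for synthetic data, optional contact
index for imports). Baseline correction subtracts the final baseline
lift's pGFR. Heaviness ratings are z-scored per subject (sample SD);
"felt" input coding classifies an object as heavy when its z-scored
rating exceeds the subject's median (a package choice — only the
binarisation point is unspecified upstream), and masks missing
ratings. The grip median split pools both sizes within subject, with
ties assigned to the low class.

Gaze: 3-frame median filter then 2nd-order 15 Hz zero-phase
Butterworth; missing samples are linearly interpolated for filtering
only and tracked as quality flags (invalid above 20% missing or a
>100 ms loss). Fixations are greedily grown windows with pitch
dispersion ≤ 3° lasting ≥ 100 ms; the pre-bounce pitch is read from
the median-filtered signal at the bounce sample, so a stationary
fixation is reported exactly. Outliers are values beyond 3.29 SD of
the pooled mean (single pass, so re-screening is idempotent); subjects
above 15% flagged-plus-missing are excluded, never silently dropped.
Gaze discretisation uses the SD of trial-to-trial pitch *changes*
within subject and condition (the changes-vs-levels ambiguity is
resolved toward changes): Δ > +1 SD → y = 1, Δ < −1 SD → y = 0,
otherwise the previous y carries forward (no belief shift), with the
first trial initialised to the modal expectation 1.

## Pipeline and problem sizes

`run_pipeline` executes simulate → fit → select → extract → compare
under a single config whose seed drives every stage; re-running a
config reproduces all outputs bit-identically (manifests carry SHA-256
checksums, priors, and every exclusion with its rule). For interception
cohorts each subject is fitted per condition and LMEs are summed over
conditions for selection. Headline analyses run at desk scale: the
model-comparison cohort uses 20 subjects × 32 trials with 4 restarts
per fit; the planted-effect demonstration uses 6 + 6 subjects × 2
conditions with 2 restarts and the HGF3/RW candidate pair, sizes at
which the planted ordering is recovered in well over 90% of seeded
replicates while a full run stays under a few seconds.

## Known limitations

Subject-level inference is MAP + Laplace, not hierarchical empirical
Bayes or MCMC; LMEs inherit Laplace's local-Gaussian assumption.
κ couplings are fixed, trading flexibility for identifiability on
short series. The learning-rate definition is an operationalisation
(the quantity is plotted but never defined upstream). Family-level
protection is the honest summary for 32-trial series; claims about
*which* HGF depth generated the data would need longer or structured
input sequences. The synthetic traces support correctness tests, not
realism claims.
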