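# Methods

## Model and procedure

### Standard analysis

Responders are defined by strict thresholding, S_i = 1 iff Y_i > d, where
Y_i is patient i's percentage reduction in PSA from baseline and d the
dichotomisation threshold (a value exactly at the threshold is a
non-responder).  The response rate estimate is p̂ = x/n and the interval is
the exact Clopper-Pearson interval computed from beta quantiles:
lower = Beta(x, n−x+1) quantile at α/2 (0 when x = 0), upper =
Beta(x+1, n−x) quantile at 1−α/2 (1 when x = n).  The beta-quantile form is
equivalent to inverting binomial tail probabilities and extends to
fractional x, which the implied-sample-size calculation exploits.

### Augmented analysis

The augmented analysis assumes the continuous data are normal after a
Box-Cox transformation and reads the response probability off the fitted
normal.  The pipeline, in order:

1. **Positive scale.**  The power transform needs strictly positive input,
   but percentage reductions span (−∞, 100].  We therefore transform to the
   PSA post/baseline ratio R_i = 1 − Y_i/100 > 0.  The threshold maps to
   r_d = 1 − d/100 and the response direction flips: response ⇔ R_i < r_d.
   The ratio is the natural positive-scale quantity for PSA data — waterfall
   distributions are well described by log-normal ratios — and this choice
   makes the subsequent log transform (λ ≈ 0) the correctly specified one
   for such data.  Complete responses (Y_i = 100, ratio 0) are floored at
   10⁻⁴ (configurable); flooring preserves classification because the
   threshold ratio is always far above the floor, and the count of floored
   values is reported in the result metadata.
2. **λ selection.**  λ maximises the Box-Cox profile log-likelihood
   −(n/2)·log Var(Z_λ) + (λ−1)·Σ log R_i over the grid [−3, 3] in steps of
   0.01, with λ = 0 meaning log.  Grid ties (rare with continuous data) are
   broken toward the λ nearest 1, preferring the least aggressive
   transform.  The grid evaluation is vectorised over λ, which keeps
   10,000-replicate simulations cheap.
3. **Transform.**  Z_i = (R_i^λ − 1)/λ (log for λ = 0), and the threshold
   is transformed with the same λ.  We use the standard centred form rather
   than R^λ/λ: the two differ by the constant 1/λ applied to both data and
   threshold, so u, p̂ and the CI are identical, and the centred form is
   continuous in λ at 0.  The transform is strictly increasing for every λ,
   so responder status survives every stage exactly (tested exhaustively).
4. **Normal fit.**  μ̂ is the sample mean, σ̂ the maximum-likelihood
   (n-divisor) standard deviation.  The n-divisor keeps the Fisher
   information variances used next internally consistent.
5. **Estimate and interval.**  With u = (d_λ − μ̂)/σ̂, the estimate is
   p̂ = Φ(u) for response-below (the ratio scale) or 1 − Φ(u) for
   response-above.  The delta method with Var(μ̂) = σ²/n, Var(σ̂) = σ²/(2n)
   and zero covariance gives SE(p̂) = φ(u)·√(1 + u²/2)/√n, and the Wald
   interval p̂ ± z_{1−α/2}·SE is truncated to [0, 1].  A logit-scale Wald
   variant is available behind a flag; the plain probability scale is the
   default.  λ is treated as fixed after selection — its estimation
   uncertainty is *not* propagated into the SE.  This is conventional for
   this family of methods and is the main known source of small-sample
   undercoverage (see Limitations).

### Efficiency metrics

Per arm, with standard and augmented 95% CI widths l_st and l_aug: the
width reduction is 100(l_st − l_aug)/l_st, and the implied sample size
n_imp solves w(m) = l_aug, where w(m) is the Clopper-Pearson width at
sample size m and the standard point estimate's response fraction.  The
default mode treats m as continuous with fractional successes x = p̂·m
(generalised beta-quantile width, Brent root-finding to 10⁻⁸ on
[n, 10⁶]); this is what reproduces one-decimal published percentages.  An
integer mode (smallest integer m with width at x = round(p̂·m) at or below
target; half-up rounding) is retained for interpretability; the two agree
within about one patient on typical inputs.  Degenerate estimates
p̂ ∈ {0, 1} use the one-sided boundary interval widths and are flagged
rather than fatal.  Gains requiring m > 10⁶ raise an error instead of
extrapolating.

## Synthetic data generator

Each arm draws a latent log-ratio L_i ~ Normal(mu_log, sigma_log²) and sets
Y_i = 100(1 − exp(L_i)).  This reproduces the structural features of
published waterfall plots — changes bounded above by 100% reduction,
right-skewed increases — and admits the closed-form truth
P(Y > d) = Φ((log(1 − d/100) − mu_log)/sigma_log), which anchors all
parameter-recovery and coverage tests.  Optional features: a clip point
(increases beyond a plot ceiling recorded at the ceiling, with the count
kept, emulating clipped waterfall bars) and a contamination mixture (a
second latent component) for probing Box-Cox robustness to
misspecification.

Corpus defaults emulate published mCRPC waterfall corpora: arm sizes
uniform on 15–45 (median ≈ 30), thresholds 30% or 50%, latent means on
[−1.2, 0.8] and SDs on [0.4, 1.2] (spreading true response rates over
roughly 0–80%), and a 30% chance of a 100%-increase clip point.  These are
fixed modelling choices, not tuning knobs.

What the generator does *not* emulate: digitisation error from reading
values off published plots, intention-to-treat denominators differing from
the plotted subset, within-patient repeated measures, and non-log-normal
ratio distributions (beyond the contamination option).  Passing tests on
this generator therefore demonstrate correctness of the procedure and its
behaviour under (near-)correct specification, not robustness to every
feature of real extracted data.

## Simulation harness and problem sizes

The Monte-Carlo harness draws arms per scenario, runs both analyses,
records CI containment of the generator truth and interval widths, and
aggregates means.  Replicate-level failures (degenerate fits; zero-width
efficiency targets at extreme thresholds) are counted and excluded from
the relevant denominators rather than aborting a scenario.  Per-scenario
seeds derive deterministically from one master seed.

Problem sizes used by the shipped tests: coverage is assessed at n = 30
with 10,000 replicates per scenario at true response rates 0.2/0.5/0.8;
parameter recovery uses single arms of n = 10⁴ on a 9-point parameter
grid; corpus-level behaviour uses a 500-arm corpus of n = 30 arms.  These
sizes give Monte-Carlo standard errors comfortably below the tolerances
being asserted.

## Numerical choices

- Grid: λ ∈ [−3, 3], step 0.01; z quantiles from the normal distribution,
  never hard-coded.
- Ratio floor 10⁻⁴ for complete responses (configurable).
- Implied-size root-finding: Brent on [n, 10⁶], tolerance 10⁻⁸.
- Medians and IQRs use linear interpolation between order statistics.
- Manifest CSV paths resolve relative to the manifest file.

## Known limitations

- **Small-sample coverage of the augmented interval.**  With λ fixed after
  selection, the Wald interval ignores λ-selection noise.  At n = 30 under
  a correctly specified latent log-normal, our simulations put augmented
  coverage near 0.90 (it is ≈ 0.94 when λ is held at its true value), so
  the interval is moderately anti-conservative at waterfall-typical arm
  sizes; coverage improves with n as λ̂ concentrates.  The efficiency
  comparison is unaffected in direction — the augmented interval is
  narrower in essentially every simulated arm.
- Two-arm comparative contrasts, multi-component responder endpoints and
  repeated-measures extensions are out of scope.
- The clipped-bar sensitivity schemes (at-clip, exponential-excess) are two
  reasonable bounds, deterministic and stochastic, not a unique definition
  of the unobserved excess beyond a plot ceiling.
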