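# augbin

Augmented (latent-normal) analysis of thresholded PSA responder endpoints,
with the standard binomial comparator and the efficiency metrics used to
compare them.

## The problem

Trials in metastatic castration-resistant prostate cancer (mCRPC) routinely
report a *PSA response rate*: the fraction of patients whose
prostate-specific antigen fell from baseline by more than a threshold *d*
(commonly a 30% or 50% reduction).  Writing *Y<sub>i</sub>* for patient
*i*'s percentage reduction, the responder indicator is
*S<sub>i</sub>* = 1 if *Y<sub>i</sub>* > *d*, else 0.  The **standard
analysis** estimates *p* = P(*S<sub>i</sub>* = 1) as
p̂ = Σ *S<sub>i</sub>* / *n* with an exact Clopper-Pearson 95% CI.
Dichotomising discards everything the continuous *Y<sub>i</sub>* know beyond
which side of the threshold they fall, and the price is precision.

The **augmented analysis** keeps the same endpoint but estimates it from the
continuous data.  The per-patient PSA post/baseline ratio
*R<sub>i</sub>* = 1 − *Y<sub>i</sub>*/100 is strictly positive; a Box-Cox
transform *Z* = (*R*<sup>λ</sup> − 1)/λ (λ = 0 meaning log) is chosen by
profile likelihood to make the data as normal as possible, the threshold is
transformed with the same λ, and a normal N(μ, σ²) is fitted by maximum
likelihood.  The response probability estimate is the fitted mass on the
response side of the transformed threshold,

&nbsp;&nbsp;&nbsp;&nbsp;p̂ = Φ(*u*),&nbsp;&nbsp; *u* = (d<sub>λ</sub> − μ̂)/σ̂,

(response on the ratio scale means *R* *below* the threshold ratio), with a
delta-method Wald interval built from

&nbsp;&nbsp;&nbsp;&nbsp;SE(p̂) = φ(*u*) · √(1 + *u*²/2) / √*n*.

Two efficiency currencies compare the methods per arm: the percentage
reduction in CI width, 100(*l*<sub>st</sub> − *l*<sub>aug</sub>)/*l*<sub>st</sub>,
and the *implied sample size* — how many patients the standard analysis
would have needed for its interval to be as narrow as the augmented one,
reported as 100(*n*<sub>imp</sub> − *n*)/*n*.

The package also ships a synthetic waterfall-plot generator (latent
log-normal ratio model with known true response probability), a corpus
re-analysis pipeline with a clipped-bar sensitivity analysis, and a
Monte-Carlo harness for coverage and efficiency studies.

## Worked example

Generate a synthetic 30-patient arm (waterfall-style, "change" orientation:
negative numbers are PSA declines) and compare both analyses at the 50%
reduction threshold:

```bash
python -c "
from augbin import SyntheticArmConfig, generate_arm, write_arm_csv
arm = generate_arm(SyntheticArmConfig(n=30, mu_log=-0.9, sigma_log=0.7,
                                      threshold=50.0, seed=11))
write_arm_csv(arm, 'example_arm.csv', orientation='change')
"
augbin compare --input example_arm.csv --threshold 50 --orientation change
```

```json
{
  "standard":  {"p_hat": 0.667, "ci_lower": 0.472, "ci_upper": 0.827, "ci_width": 0.355},
  "augmented": {"p_hat": 0.685, "ci_lower": 0.551, "ci_upper": 0.820, "ci_width": 0.269,
                "lambda": 0.08},
  "efficiency": {"width_reduction_pct": 24.4, "n_implied": 52.2, "ss_increase_pct": 73.9}
}
```

(Abridged; the command prints the full JSON.)  Reading: 20 of 30 patients
responded, so the standard estimate is 66.7% with an exact CI of
(47.2%, 82.7%).  The augmented analysis — which here selected λ = 0.08,
essentially a log transform — estimates 68.5% with CI (55.1%, 82.0%), a
24.4% narrower interval.  The standard analysis would have needed about 52
patients (a 73.9% increase) to be that precise.

Other entry points:

```bash
augbin analyse --method augmented --input arm.csv --threshold 50 --orientation change
augbin simulate corpus --arms 78 --seed 1 --outdir corpus/
augbin corpus --manifest corpus/manifest.csv --out summary.json --per-arm per_arm.csv
augbin sensitivity --input arm.csv --threshold 50 --orientation change \
    --clip-point 100 --n-clipped 3 --scheme exponential-excess --reps 200 --seed 7
```

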