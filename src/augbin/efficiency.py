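"""Efficiency metrics comparing the standard and augmented analyses.

Two currencies are used:

* the percentage reduction in the 95% CI width, ``100(l_st - l_aug)/l_st``;
* the implied sample size: how many patients the standard analysis would
  have needed for its Clopper-Pearson interval, at the observed response
  fraction, to be as narrow as the augmented one, reported as the
  percentage increase ``100(n_imp - n)/n``.

The default "continuous" mode treats the sample size m as a real number
with fractional successes x = p̂·m, using the generalised beta-quantile
Clopper-Pearson width; this reproduces one-decimal percentage gains.  An
"integer" mode (smallest integer m with width at round(p̂·m) at or below
target) is kept for interpretability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from scipy.optimize import brentq

from .data_model import ResponseAnalysisResult
from .standard_analysis import clopper_pearson_ci

__all__ = ["EfficiencyComparison", "ci_width_reduction", "implied_sample_size", "compare"]

#: Sample sizes are searched on [n, SEARCH_CEILING]; gains beyond the
#: ceiling are reported as an error rather than extrapolated.
SEARCH_CEILING = 1_000_000

Mode = Literal["integer", "continuous"]


@dataclass(frozen=True)
class EfficiencyComparison:
    """Width-reduction and implied-sample-size gains for one arm."""

    width_reduction_pct: float
    n_implied: float
    ss_increase_pct: float
    mode: Mode
    boundary: bool = False  # p_hat was 0 or 1; one-sided widths were used

    def to_dict(self) -> dict:
        return {
            "width_reduction_pct": self.width_reduction_pct,
            "n_implied": self.n_implied,
            "ss_increase_pct": self.ss_increase_pct,
            "mode": self.mode,
            "boundary": self.boundary,
        }


def ci_width_reduction(l_st: float, l_aug: float) -> float:
    """Percentage change in CI width, 100(l_st - l_aug)/l_st."""
    if l_st <= 0:
        raise ValueError("standard CI width must be positive")
    if l_aug < 0:
        raise ValueError("augmented CI width cannot be negative")
    return 100.0 * (l_st - l_aug) / l_st


def _cp_width(p_hat: float, m: float, level: float, mode: Mode) -> float:
    """Clopper-Pearson width at sample size m and response fraction p_hat."""
    if mode == "integer":
        x = int(p_hat * m + 0.5)  # round half-up
        x = min(max(x, 0), int(m))
    else:
        x = p_hat * m
    lo, hi = clopper_pearson_ci(x, m, level)
    return hi - lo


def implied_sample_size(
    p_hat: float,
    n: int,
    l_target: float,
    level: float = 0.95,
    mode: Mode = "continuous",
) -> EfficiencyComparison:
    """Sample size at which the standard CI would match a target width.

    In continuous mode the generalised Clopper-Pearson width w(m) (beta
    quantiles with fractional successes p̂·m) is root-solved for
    w(m) = l_target on [n, 10⁶]; in integer mode the smallest integer
    m >= n with width at or below the target is returned.  Degenerate
    p̂ ∈ {0, 1} is handled with the one-sided boundary interval widths and
    flagged.
    """
    if l_target <= 0:
        raise ValueError("target width must be positive")
    if not (0 <= p_hat <= 1):
        raise ValueError("p_hat must lie in [0, 1]")
    boundary = p_hat in (0.0, 1.0)

    width_at_n = _cp_width(p_hat, n, level, "integer" if mode == "integer" else "continuous")
    if width_at_n <= l_target:
        # target at least as wide as the achieved width: no gain
        return EfficiencyComparison(
            width_reduction_pct=ci_width_reduction(width_at_n, l_target),
            n_implied=float(n),
            ss_increase_pct=0.0,
            mode=mode,
            boundary=boundary,
        )

    if mode == "continuous":
        f = lambda m: _cp_width(p_hat, m, level, "continuous") - l_target
        if f(SEARCH_CEILING) > 0:
            raise ValueError(
                f"no sample size below {SEARCH_CEILING} attains width {l_target}"
            )
        # w(m) is continuous and decreasing in m, so the root is bracketed
        m_imp = brentq(f, n, SEARCH_CEILING, xtol=1e-8)
        n_imp = float(m_imp)
    else:
        n_imp = None
        for m in range(n, SEARCH_CEILING + 1):
            if _cp_width(p_hat, m, level, "integer") <= l_target:
                n_imp = float(m)
                break
        if n_imp is None:
            raise ValueError(
                f"no sample size below {SEARCH_CEILING} attains width {l_target}"
            )

    return EfficiencyComparison(
        width_reduction_pct=ci_width_reduction(width_at_n, l_target),
        n_implied=n_imp,
        ss_increase_pct=100.0 * (n_imp - n) / n,
        mode=mode,
        boundary=boundary,
    )


def compare(
    standard: ResponseAnalysisResult,
    augmented: ResponseAnalysisResult,
    mode: Mode = "continuous",
) -> EfficiencyComparison:
    """Both efficiency metrics for one arm's pair of analysis results.

    The implied sample size uses the standard point estimate and the
    augmented interval's width as the target, matching how the gains are
    quoted in re-analyses of published arms.
    """
    if standard.n != augmented.n:
        raise ValueError(
            f"results come from different sample sizes ({standard.n} != {augmented.n})"
        )
    l_st, l_aug = standard.ci_width, augmented.ci_width
    eff = implied_sample_size(
        standard.p_hat, standard.n, l_aug, level=standard.level, mode=mode
    )
    return EfficiencyComparison(
        width_reduction_pct=ci_width_reduction(l_st, l_aug),
        n_implied=eff.n_implied,
        ss_increase_pct=eff.ss_increase_pct,
        mode=mode,
        boundary=eff.boundary,
    )
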