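"""Standard binomial responder analysis: p̂ = x/n with an exact
Clopper-Pearson confidence interval.

The Clopper-Pearson interval is computed from beta quantiles,
``lower = Beta(x, n-x+1).ppf(α/2)`` and ``upper = Beta(x+1, n-x).ppf(1-α/2)``,
with the usual boundary conventions ``lower = 0`` at ``x = 0`` and
``upper = 1`` at ``x = n``.  This parameterisation extends naturally to
fractional "successes", which the efficiency module relies on when treating
the sample size as continuous.
"""

from __future__ import annotations

from scipy.stats import beta

from .data_model import (
    PSAChangeDataset,
    ResponseAnalysisResult,
    classify_responders,
)

__all__ = ["standard_estimate", "clopper_pearson_ci", "standard_analysis"]


def standard_estimate(x: float, n: int) -> float:
    """Responder proportion x/n."""
    if n < 1:
        raise ValueError("sample size must be at least 1")
    if not (0 <= x <= n):
        raise ValueError("responder count must satisfy 0 <= x <= n")
    return x / n


def clopper_pearson_ci(
    x: float, n: float, level: float = 0.95
) -> tuple[float, float]:
    """Exact (conservative) binomial interval from beta quantiles.

    ``x`` may be fractional, giving the generalised interval used when the
    sample size is treated as a continuous quantity.
    """
    if not (0 < level < 1):
        raise ValueError("confidence level must lie strictly in (0, 1)")
    if n < 1:
        raise ValueError("sample size must be at least 1")
    if not (0 <= x <= n):
        raise ValueError("responder count must satisfy 0 <= x <= n")
    alpha = 1.0 - level
    lower = 0.0 if x <= 0 else float(beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x >= n else float(beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


def standard_analysis(
    dataset: PSAChangeDataset, level: float = 0.95
) -> ResponseAnalysisResult:
    """Classify responders and report the binomial estimate with its CI."""
    responders = classify_responders(dataset)
    x, n = responders.count, responders.n
    lower, upper = clopper_pearson_ci(x, n, level)
    return ResponseAnalysisResult(
        method="standard",
        p_hat=standard_estimate(x, n),
        ci_lower=lower,
        ci_upper=upper,
        level=level,
        n=n,
        metadata={"responders": x},
    )
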