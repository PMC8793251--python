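"""Augmented latent-normal analysis of a thresholded responder endpoint.

Instead of reducing each patient to a binary responder indicator, the
augmented analysis models the underlying continuous PSA change.  The
pipeline is:

1. Map percentage reductions ``Y_i`` to the strictly positive post/baseline
   PSA ratio ``R_i = 1 - Y_i/100`` (a 60% reduction is a ratio of 0.4; a 40%
   increase is 1.4).  The response threshold maps to ``r_d = 1 - d/100`` and
   the response direction flips: a response is now ``R_i < r_d``.
2. Select a Box-Cox exponent λ by maximising the profile log-likelihood on a
   grid, and transform data and threshold with the same λ.  The transform is
   strictly increasing for every λ, so responder status is preserved
   exactly.
3. Fit a normal distribution N(μ, σ²) to the transformed values by maximum
   likelihood (σ̂ uses the n-divisor).
4. Estimate the response probability as the fitted normal mass on the
   response side of the transformed threshold, p̂ = Φ(u) with
   u = (d_λ - μ̂)/σ̂ when the response direction is "below" (the ratio
   scale) or 1 - Φ(u) for "above".
5. Form a Wald confidence interval via the delta method.  With the
   information-matrix variances Var(μ̂) = σ²/n, Var(σ̂) = σ²/(2n) and zero
   covariance, the standard error of p̂ is

       SE(p̂) = φ(u) · sqrt(1 + u²/2) / sqrt(n).

λ is treated as fixed after selection; its estimation uncertainty is not
propagated into the interval (a known limitation of this class of method).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.stats import norm

from .data_model import PSAChangeDataset, ResponseAnalysisResult

__all__ = [
    "BoxCoxFit",
    "NormalFit",
    "DegenerateDataError",
    "to_positive_scale",
    "select_lambda",
    "boxcox_transform",
    "fit_normal",
    "augmented_response_estimate",
    "delta_method_ci",
    "augmented_analysis",
]

#: Default floor for the PSA ratio when a patient's PSA disappeared entirely
#: (Y = 100 ⇒ ratio 0, which no power transform can accept).
RATIO_FLOOR = 1e-4

#: Box-Cox selection grid.
LAMBDA_GRID = np.round(np.arange(-3.0, 3.0 + 1e-9, 0.01), 10)

Direction = Literal["above", "below"]


class DegenerateDataError(ValueError):
    """Raised when the data carry no usable variation for the normal fit."""


@dataclass(frozen=True)
class BoxCoxFit:
    """A Box-Cox transform applied jointly to data and threshold."""

    lam: float
    transformed_values: np.ndarray
    transformed_threshold: float
    scale_used: Literal["ratio", "shifted-raw"]
    direction: Direction


@dataclass(frozen=True)
class NormalFit:
    """Maximum-likelihood normal fit (σ̂ with divisor n)."""

    mu: float
    sigma: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise DegenerateDataError("normal fit needs at least 3 values")
        if not self.sigma > 0:
            raise DegenerateDataError("all transformed values identical")


def to_positive_scale(
    dataset: PSAChangeDataset, floor: float = RATIO_FLOOR
) -> tuple[np.ndarray, float, Direction, int]:
    """Percentage reductions → strictly positive PSA post/baseline ratios.

    Returns ``(ratios, threshold_ratio, direction, n_floored)``.  Ratios of
    complete responders (Y = 100) are floored at ``floor``; the response
    threshold is always interior so classification is unchanged.
    """
    ratios = 1.0 - dataset.values / 100.0
    n_floored = int(np.sum(ratios < floor))
    ratios = np.maximum(ratios, floor)
    r_d = 1.0 - dataset.threshold / 100.0
    return ratios, r_d, "below", n_floored


def boxcox_profile_llf(lams: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Box-Cox profile log-likelihood at each λ (vectorised over the grid).

    Profiling out μ and σ leaves, up to an additive constant,
    ``-n/2 · log(Var_λ) + (λ - 1)·Σ log x``, where Var_λ is the n-divisor
    variance of the transformed data and the second term is the Jacobian
    of the transform.
    """
    lams = np.atleast_1d(np.asarray(lams, dtype=float))
    logx = np.log(np.asarray(values, dtype=float))
    n = logx.size
    # z[k, i] = transform of x_i at lams[k]; λ = 0 is the log limit
    with np.errstate(over="ignore"):
        z = np.exp(np.outer(lams, logx))
    nonzero = lams != 0.0
    z[nonzero] = (z[nonzero] - 1.0) / lams[nonzero, None]
    z[~nonzero] = logx
    var = z.var(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        llf = -0.5 * n * np.log(var) + (lams - 1.0) * logx.sum()
    return np.where(np.isfinite(llf), llf, -np.inf)


def select_lambda(
    values: np.ndarray, grid: np.ndarray | None = None
) -> float:
    """Box-Cox exponent maximising the profile log-likelihood on a grid.

    The profile log-likelihood at λ is the normal log-likelihood of the
    transformed data (with MLE μ, σ) plus the Jacobian term
    (λ - 1)·Σ log R_i.  Ties are broken toward the λ nearest 1, preferring
    the least aggressive transformation.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise DegenerateDataError("lambda selection needs at least 3 values")
    if np.any(values <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if np.ptp(values) == 0:
        raise DegenerateDataError("constant input: no transform is defined")
    if grid is None:
        grid = LAMBDA_GRID
    llf = boxcox_profile_llf(grid, values)
    best = llf.max()
    # floating-point ties: everything within a hair of the maximum competes
    candidates = grid[llf >= best - 1e-10]
    return float(candidates[np.argmin(np.abs(candidates - 1.0))])


def _boxcox(values: np.ndarray | float, lam: float) -> np.ndarray | float:
    if lam == 0.0:
        return np.log(values)
    return (np.power(values, lam) - 1.0) / lam


def boxcox_transform(
    values: np.ndarray,
    threshold: float,
    lam: float,
    direction: Direction = "below",
    scale_used: Literal["ratio", "shifted-raw"] = "ratio",
) -> BoxCoxFit:
    """Apply the Box-Cox transform with exponent λ to data and threshold.

    Uses the standard form (x^λ - 1)/λ, continuous in λ at 0 (where it is
    the log).  It differs from x^λ/λ only by a constant shift applied to
    both the data and the threshold, so downstream estimates are identical.
    The transform is strictly increasing for every λ, hence the responder
    direction is unchanged.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0) or threshold <= 0:
        raise ValueError("Box-Cox requires strictly positive data and threshold")
    return BoxCoxFit(
        lam=float(lam),
        transformed_values=np.asarray(_boxcox(values, lam), dtype=float),
        transformed_threshold=float(_boxcox(threshold, lam)),
        scale_used=scale_used,
        direction=direction,
    )


def fit_normal(values: np.ndarray) -> NormalFit:
    """Normal MLE: sample mean and n-divisor standard deviation."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise DegenerateDataError("normal fit needs at least 3 values")
    mu = float(values.mean())
    sigma = float(values.std(ddof=0))
    return NormalFit(mu=mu, sigma=sigma, n=int(values.size))


def augmented_response_estimate(
    fit: NormalFit, threshold: float, direction: Direction
) -> float:
    """Fitted-normal mass on the response side of the threshold."""
    u = (threshold - fit.mu) / fit.sigma
    p = norm.cdf(u)
    return float(p if direction == "below" else 1.0 - p)


def delta_method_se(fit: NormalFit, threshold: float) -> float:
    """Delta-method standard error of the response-probability estimate.

    p̂ is φ-smooth in (μ̂, σ̂); with Var(μ̂) = σ²/n, Var(σ̂) = σ²/(2n) and
    asymptotic independence, SE(p̂) = φ(u)·sqrt(1 + u²/2)/sqrt(n).  The SE
    is the same for either response direction.
    """
    u = (threshold - fit.mu) / fit.sigma
    return float(norm.pdf(u) * np.sqrt(1.0 + u * u / 2.0) / np.sqrt(fit.n))


def delta_method_ci(
    fit: NormalFit,
    threshold: float,
    direction: Direction,
    level: float = 0.95,
    logit_scale: bool = False,
) -> tuple[float, float]:
    """Wald interval for the response probability, truncated to [0, 1].

    With ``logit_scale=True`` the interval is instead formed on the logit
    scale and back-transformed (never truncates, but is not the default).
    """
    if not (0 < level < 1):
        raise ValueError("confidence level must lie strictly in (0, 1)")
    p = augmented_response_estimate(fit, threshold, direction)
    se = delta_method_se(fit, threshold)
    z = norm.ppf(1 - (1 - level) / 2)
    if logit_scale:
        if p <= 0.0 or p >= 1.0:
            # logit undefined at the boundary; degenerate interval at p
            return float(p), float(p)
        eta = np.log(p / (1 - p))
        se_eta = se / (p * (1 - p))
        lo, hi = eta - z * se_eta, eta + z * se_eta
        expit = lambda t: 1.0 / (1.0 + np.exp(-t))
        return float(expit(lo)), float(expit(hi))
    return max(0.0, p - z * se), min(1.0, p + z * se)


def augmented_analysis(
    dataset: PSAChangeDataset,
    level: float = 0.95,
    *,
    floor: float = RATIO_FLOOR,
    logit_scale: bool = False,
) -> ResponseAnalysisResult:
    """Full augmented pipeline: ratio scale → Box-Cox → normal fit → Wald CI.

    The selected λ, the scale used, and the number of floored complete
    responses are recorded in the result metadata.
    """
    if dataset.n < 3:
        raise DegenerateDataError("augmented analysis needs at least 3 values")
    ratios, r_d, direction, n_floored = to_positive_scale(dataset, floor=floor)
    try:
        lam = select_lambda(ratios)
    except DegenerateDataError as err:
        raise DegenerateDataError(f"lambda selection: {err}") from err
    bc = boxcox_transform(ratios, r_d, lam, direction=direction)
    try:
        fit = fit_normal(bc.transformed_values)
    except DegenerateDataError as err:
        raise DegenerateDataError(f"normal fit: {err}") from err
    p_hat = augmented_response_estimate(fit, bc.transformed_threshold, direction)
    lower, upper = delta_method_ci(
        fit, bc.transformed_threshold, direction, level, logit_scale=logit_scale
    )
    return ResponseAnalysisResult(
        method="augmented",
        p_hat=p_hat,
        ci_lower=lower,
        ci_upper=upper,
        level=level,
        n=dataset.n,
        metadata={
            "lambda": lam,
            "scale_used": "ratio",
            "floored_count": n_floored,
            "mu": fit.mu,
            "sigma": fit.sigma,
        },
    )
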