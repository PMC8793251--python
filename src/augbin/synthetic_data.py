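"""Synthetic waterfall-style PSA change data with known ground truth.

The generator uses a latent log-normal ratio model: each patient's
post/baseline PSA ratio is ``exp(L)`` with ``L ~ Normal(mu_log,
sigma_log²)``, so the percentage reduction is ``Y = 100(1 - exp(L))``.
This reproduces the salient features of published waterfall plots —
percentage changes bounded above by a 100% reduction, right-skewed
increases, and a closed-form true response probability

    P(Y > d) = Φ((log(1 - d/100) - mu_log) / sigma_log).

An optional contamination component (a second latent normal mixed in with
probability ``contamination``) lets tests probe robustness of the Box-Cox
step to model misspecification, and an optional clip point emulates
waterfall bars truncated at a plot ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .data_model import PSAChangeDataset, write_arm_csv, write_manifest

__all__ = [
    "SyntheticArmConfig",
    "generate_arm",
    "true_response_probability",
    "generate_corpus",
]


@dataclass(frozen=True)
class SyntheticArmConfig:
    """Latent log-normal ratio model for one synthetic trial arm.

    ``mu_log`` and ``sigma_log`` parameterise the latent log-ratio ``L``;
    ``threshold`` is the response threshold d in percent; ``clip_point``
    (percent increase) truncates large increases as waterfall plots do.
    ``contamination`` mixes in a second latent component
    Normal(contam_mu_log, contam_sigma_log²) with the given probability.
    """

    n: int
    mu_log: float
    sigma_log: float
    threshold: float = 50.0
    clip_point: float | None = None
    seed: int = 0
    arm_label: str = "synthetic"
    contamination: float = 0.0
    contam_mu_log: float = 0.5
    contam_sigma_log: float = 0.25

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("arm size must be at least 3")
        if not self.sigma_log > 0:
            raise ValueError("sigma_log must be positive")
        if not (0.0 <= self.contamination < 1.0):
            raise ValueError("contamination must lie in [0, 1)")


def generate_arm(config: SyntheticArmConfig) -> PSAChangeDataset:
    """Draw one arm; deterministic under the config's seed."""
    rng = np.random.default_rng(config.seed)
    latent = rng.normal(config.mu_log, config.sigma_log, size=config.n)
    if config.contamination > 0:
        mask = rng.random(config.n) < config.contamination
        latent[mask] = rng.normal(
            config.contam_mu_log, config.contam_sigma_log, size=int(mask.sum())
        )
    values = 100.0 * (1.0 - np.exp(latent))
    n_clipped = 0
    if config.clip_point is not None:
        # increases beyond the ceiling are recorded at the ceiling
        clipped = -values > config.clip_point
        n_clipped = int(clipped.sum())
        values[clipped] = -config.clip_point
    return PSAChangeDataset(
        values=values,
        threshold=config.threshold,
        arm_label=config.arm_label,
        n_clipped=n_clipped,
        clip_point=config.clip_point,
        orientation_note="reduction",
    )


def true_response_probability(config: SyntheticArmConfig) -> float:
    """Exact P(Y > d) under the (uncontaminated) latent model.

    Clipping does not affect the truth: clipped bars are increases, always
    on the non-responder side of any reduction threshold.
    """
    if config.threshold >= 100.0:
        return 0.0
    z = (np.log(1.0 - config.threshold / 100.0) - config.mu_log) / config.sigma_log
    p_main = norm.cdf(z)
    if config.contamination == 0.0:
        return float(p_main)
    zc = (
        np.log(1.0 - config.threshold / 100.0) - config.contam_mu_log
    ) / config.contam_sigma_log
    return float(
        (1 - config.contamination) * p_main + config.contamination * norm.cdf(zc)
    )


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

#: Defaults emulating the statistical structure of published mCRPC waterfall
#: corpora: arm sizes with median ≈ 30, thresholds of 30% or 50% reduction,
#: and latent parameters spreading response rates over roughly 0–80%.
DEFAULT_N_RANGE = (15, 45)
DEFAULT_MU_LOG_RANGE = (-1.2, 0.8)
DEFAULT_SIGMA_LOG_RANGE = (0.4, 1.2)
DEFAULT_THRESHOLDS = (30.0, 50.0)
DEFAULT_CLIP_PROB = 0.3
DEFAULT_CLIP_POINT = 100.0


def generate_corpus(
    n_arms: int,
    seed: int,
    *,
    n_range: tuple[int, int] = DEFAULT_N_RANGE,
    mu_log_range: tuple[float, float] = DEFAULT_MU_LOG_RANGE,
    sigma_log_range: tuple[float, float] = DEFAULT_SIGMA_LOG_RANGE,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    clip_prob: float = DEFAULT_CLIP_PROB,
    clip_point: float = DEFAULT_CLIP_POINT,
    outdir: str | Path | None = None,
) -> tuple[list[PSAChangeDataset], list[SyntheticArmConfig], "object"]:
    """Draw a corpus of synthetic arms; optionally write CSVs + manifest.

    Returns ``(datasets, configs, manifest)`` where the manifest is a
    pandas DataFrame in the standard corpus dialect (paths filled in only
    when ``outdir`` is given).
    """
    import pandas as pd

    if n_arms < 1:
        raise ValueError("need at least one arm")
    rng = np.random.default_rng(seed)
    datasets, configs, rows = [], [], []
    for k in range(n_arms):
        cfg = SyntheticArmConfig(
            n=int(rng.integers(n_range[0], n_range[1] + 1)),
            mu_log=float(rng.uniform(*mu_log_range)),
            sigma_log=float(rng.uniform(*sigma_log_range)),
            threshold=float(rng.choice(np.asarray(thresholds, dtype=float))),
            clip_point=clip_point if rng.random() < clip_prob else None,
            seed=int(rng.integers(0, 2**31 - 1)),
            arm_label=f"arm_{k:03d}",
        )
        ds = generate_arm(cfg)
        datasets.append(ds)
        configs.append(cfg)
        rows.append(
            {
                "arm_label": cfg.arm_label,
                "path": f"{cfg.arm_label}.csv",
                "threshold": cfg.threshold,
                "orientation": "reduction",
                "n_clipped": ds.n_clipped,
                "clip_point": ds.clip_point,
            }
        )
    manifest = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for ds, row in zip(datasets, rows):
            write_arm_csv(ds, outdir / row["path"])
        write_manifest(rows, outdir / "manifest.csv")
    return datasets, configs, manifest
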