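"""Core domain types and CSV I/O for per-arm PSA change-from-baseline data.

Conventions
-----------
The internal canonical scale is the *percentage reduction* in PSA from
baseline, written ``Y_i``: positive values are declines, negative values are
increases, and no value can exceed 100 (PSA cannot fall by more than 100%).
Published waterfall plots usually store the opposite sign ("percentage
change", negative = decline), so every reader takes an explicit
``orientation`` flag; there is no auto-detection, because a silent sign flip
is worse than an error.

A patient is a responder exactly when ``Y_i > d`` for the arm's
dichotomisation threshold ``d`` — the inequality is strict, so a value
sitting exactly on the threshold is a non-responder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PSAChangeDataset",
    "ResponderVector",
    "ResponseAnalysisResult",
    "Orientation",
    "read_arm_csv",
    "write_arm_csv",
    "classify_responders",
    "read_manifest",
    "write_manifest",
]

#: Column name used in single-arm CSV files.
ARM_CSV_COLUMN = "psa_change"

#: Columns of a corpus manifest, in order.
MANIFEST_COLUMNS = [
    "arm_label",
    "path",
    "threshold",
    "orientation",
    "n_clipped",
    "clip_point",
]

Orientation = Literal["reduction", "change"]


class DatasetValidationError(ValueError):
    """Raised when an arm dataset violates a structural invariant."""


@dataclass(frozen=True)
class PSAChangeDataset:
    """One trial arm's continuous PSA percentage reductions plus metadata.

    Parameters
    ----------
    values
        Per-patient percentage reductions ``Y_i`` (positive = decline, %).
    threshold
        Response threshold ``d`` in percent; response iff ``Y_i > d``.
    arm_label
        Free-text identifier for the arm.
    n_clipped
        Number of waterfall bars truncated at the plot ceiling.
    clip_point
        The ceiling as a percentage *increase* (``None`` if no clipping).
    orientation_note
        Orientation the source file used ("reduction" or "change").
    """

    values: np.ndarray
    threshold: float
    arm_label: str = "arm"
    n_clipped: int = 0
    clip_point: float | None = None
    orientation_note: Orientation = "reduction"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size == 0:
            raise DatasetValidationError("values must be a non-empty 1-d vector")
        if not np.all(np.isfinite(vals)):
            raise DatasetValidationError("values must all be finite")
        if np.any(vals > 100.0):
            raise DatasetValidationError(
                "PSA cannot fall more than 100%: found reduction "
                f"{vals.max():g} > 100"
            )
        if self.n_clipped < 0:
            raise DatasetValidationError("n_clipped must be non-negative")
        if self.n_clipped > vals.size:
            raise DatasetValidationError("n_clipped exceeds number of values")
        if not np.isfinite(self.threshold):
            raise DatasetValidationError("threshold must be finite")

    @property
    def n(self) -> int:
        return int(self.values.size)

    def with_values(self, values: Sequence[float]) -> "PSAChangeDataset":
        """Copy of the dataset with ``values`` replaced (re-validated)."""
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class ResponderVector:
    """Binary responder indicators ``S_i`` (1 = responder)."""

    indicators: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.indicators, dtype=int)
        if not np.isin(s, (0, 1)).all():
            raise DatasetValidationError("indicators must be 0/1")
        object.__setattr__(self, "indicators", s)

    @property
    def n(self) -> int:
        return int(self.indicators.size)

    @property
    def count(self) -> int:
        """Number of responders, sum of the S_i."""
        return int(self.indicators.sum())


@dataclass(frozen=True)
class ResponseAnalysisResult:
    """Point estimate and confidence interval for a response probability."""

    method: Literal["standard", "augmented"]
    p_hat: float
    ci_lower: float
    ci_upper: float
    level: float
    n: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_hat <= 1.0):
            raise ValueError("p_hat must lie in [0, 1]")
        if not (0.0 <= self.ci_lower <= self.ci_upper <= 1.0):
            raise ValueError("require 0 <= ci_lower <= ci_upper <= 1")

    @property
    def ci_width(self) -> float:
        return self.ci_upper - self.ci_lower

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "p_hat": self.p_hat,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "ci_width": self.ci_width,
            "level": self.level,
            "n": self.n,
        }
        d.update(self.metadata)
        return d


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def _parse_column(path: Path) -> np.ndarray:
    """Read the single numeric column, tolerating an optional header row."""
    try:
        raw = path.read_text(encoding="utf-8")
    except FileNotFoundError:
        raise FileNotFoundError(f"arm CSV not found: {path}") from None
    rows = [line.strip() for line in raw.splitlines() if line.strip()]
    if not rows:
        raise DatasetValidationError(f"empty arm CSV: {path}")
    start = 0
    try:
        float(rows[0])
    except ValueError:
        # header row (e.g. "psa_change")
        start = 1
    if start == len(rows):
        raise DatasetValidationError(f"arm CSV has a header but no data: {path}")
    out = np.empty(len(rows) - start)
    for i, row in enumerate(rows[start:], start=start):
        try:
            out[i - start] = float(row)
        except ValueError:
            raise DatasetValidationError(
                f"non-numeric value {row!r} at row {i + 1} of {path}"
            ) from None
    return out


def read_arm_csv(
    path: str | Path,
    threshold: float,
    orientation: Orientation,
    *,
    arm_label: str | None = None,
    n_clipped: int = 0,
    clip_point: float | None = None,
) -> PSAChangeDataset:
    """Read one arm's values, normalising to the reduction convention.

    ``orientation="change"`` means the file stores percentage change
    (negative = decline); those values are negated on read so that the
    returned dataset always holds percentage reductions.
    """
    if orientation not in ("reduction", "change"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    values = _parse_column(path)
    if orientation == "change":
        values = -values
    return PSAChangeDataset(
        values=values,
        threshold=float(threshold),
        arm_label=arm_label if arm_label is not None else path.stem,
        n_clipped=n_clipped,
        clip_point=clip_point,
        orientation_note=orientation,
    )


def write_arm_csv(
    dataset: PSAChangeDataset,
    path: str | Path,
    orientation: Orientation = "reduction",
) -> Path:
    """Write the arm's values as a one-column CSV in the given orientation."""
    path = Path(path)
    vals = dataset.values if orientation == "reduction" else -dataset.values
    pd.DataFrame({ARM_CSV_COLUMN: vals}).to_csv(path, index=False)
    return path


def classify_responders(dataset: PSAChangeDataset) -> ResponderVector:
    """S_i = 1 iff Y_i > d, with strict inequality at the threshold."""
    return ResponderVector((dataset.values > dataset.threshold).astype(int))


# ---------------------------------------------------------------------------
# Corpus manifest
# ---------------------------------------------------------------------------

def write_manifest(rows: Iterable[dict], path: str | Path) -> Path:
    """Write a corpus manifest CSV (columns fixed by MANIFEST_COLUMNS)."""
    path = Path(path)
    df = pd.DataFrame(list(rows))
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest rows missing columns: {sorted(missing)}")
    df[MANIFEST_COLUMNS].to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a corpus manifest; paths are resolved relative to the manifest."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    df = df.copy()
    df["path"] = [str((path.parent / p).resolve()) for p in df["path"]]
    df["n_clipped"] = df["n_clipped"].fillna(0).astype(int)
    return df


def load_manifest_arm(row: pd.Series | dict) -> PSAChangeDataset:
    """Load one manifest row as a validated dataset."""
    clip = row["clip_point"]
    if clip is not None and pd.isna(clip):
        clip = None
    return read_arm_csv(
        row["path"],
        threshold=float(row["threshold"]),
        orientation=row["orientation"],
        arm_label=str(row["arm_label"]),
        n_clipped=int(row["n_clipped"]),
        clip_point=None if clip is None else float(clip),
    )
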