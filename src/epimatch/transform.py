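"""Score adjustment onto the 0-6 mismatch scale, categorisation, correlation.

Raw epitope-load counts live on a much wider scale (0 to a few hundred)
than the 0-6 antigen-mismatch count, and their hazard contribution is
empirically logarithmic. To make per-unit hazard ratios comparable, a
cohort's raw scores are mapped by

    adjusted_i = ln(raw_i + 1) * 6 / max_j ln(raw_j + 1)

so that a raw score of 0 maps to 0 and the cohort maximum maps to 6.
The cohort maximum is part of the fitted transform and is stored in an
:class:`AdjustmentContext` so the identical mapping can be applied to new
data (e.g. at allocation time) without refitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import stats

SCALE_TOP = 6.0


class AdjustmentError(ValueError):
    """Adjustment undefined (e.g. all raw scores zero)."""


@dataclass(frozen=True)
class AdjustmentContext:
    """Fitted parameters of the log adjustment.

    ``cohort_max_log`` is max ln(raw+1) over the cohort the transform was
    fitted on; ``scale_top`` is the top of the mismatch scale (6).
    """

    cohort_max_log: float
    scale_top: float = SCALE_TOP

    def apply(self, raw: Sequence[float] | np.ndarray | float) -> np.ndarray | float:
        """Apply the stored transform to raw scores (scalar or vector)."""
        arr = np.asarray(raw, dtype=float)
        if np.any(arr < 0):
            raise AdjustmentError("raw scores must be non-negative")
        out = np.log1p(arr) * self.scale_top / self.cohort_max_log
        return float(out) if np.isscalar(raw) else out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {"cohort_max_log": self.cohort_max_log, "scale_top": self.scale_top}
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "AdjustmentContext":
        d = yaml.safe_load(Path(path).read_text())
        return cls(cohort_max_log=float(d["cohort_max_log"]), scale_top=float(d["scale_top"]))


def adjust_scores(
    raw_scores: Sequence[float] | np.ndarray, scale_top: float = SCALE_TOP
) -> tuple[np.ndarray, AdjustmentContext]:
    """Fit and apply the log adjustment to a cohort of raw scores.

    Returns the adjusted vector (each value in [0, scale_top]) and the
    fitted :class:`AdjustmentContext`. Raises if every raw score is zero,
    in which case the normalising maximum vanishes.
    """
    arr = np.asarray(raw_scores, dtype=float)
    if arr.size == 0:
        raise AdjustmentError("empty score vector")
    if np.any(arr < 0):
        raise AdjustmentError("raw scores must be non-negative")
    max_log = float(np.max(np.log1p(arr)))
    if max_log <= 0.0:
        raise AdjustmentError("all raw scores are zero; adjustment undefined")
    ctx = AdjustmentContext(cohort_max_log=max_log, scale_top=scale_top)
    return ctx.apply(arr), ctx


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered, gap-free categories over [0, inf) with inclusive upper bounds."""

    labels: tuple[str, ...]
    uppers: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.uppers):
            raise ValueError("labels and uppers must have equal length")
        if any(b <= a for a, b in zip(self.uppers, self.uppers[1:])):
            raise ValueError("category upper bounds must be strictly increasing")

    def __len__(self) -> int:
        return len(self.labels)

    def assign(self, value: float) -> str:
        if value < 0:
            raise ValueError(f"negative value {value} cannot be categorized")
        for label, hi in zip(self.labels, self.uppers):
            if value <= hi:
                return label
        return self.labels[-1]

    # -- standard schemes ------------------------------------------------
    @classmethod
    def pirche_seven(cls) -> "CategoryScheme":
        """The seven raw-score categories: 0-1, 2-12, ..., 69-102, >102."""
        return cls(
            labels=("0-1", "2-12", "13-25", "26-43", "44-68", "69-102", ">102"),
            uppers=(1, 12, 25, 43, 68, 102, math.inf),
        )

    @classmethod
    def hla_seven(cls) -> "CategoryScheme":
        """One category per mismatch count 0..6."""
        return cls(labels=tuple(str(k) for k in range(7)), uppers=tuple(range(7)))

    @classmethod
    def pirche_low_high(cls) -> "CategoryScheme":
        return cls(labels=("0-12", ">12"), uppers=(12, math.inf))

    @classmethod
    def pirche_three(cls) -> "CategoryScheme":
        return cls(labels=("0-12", "13-68", "69-211"), uppers=(12, 68, math.inf))

    @classmethod
    def hla_low_high(cls) -> "CategoryScheme":
        return cls(labels=("0-3", "4-6"), uppers=(3, 6))


def categorize(values: Sequence[float] | np.ndarray, scheme: CategoryScheme) -> list[str]:
    """Assign each value its category label (upper bounds inclusive)."""
    return [scheme.assign(float(v)) for v in np.asarray(values, dtype=float)]


def similarly_sized_boundaries(
    values: Sequence[float] | np.ndarray, group_sizes: Sequence[int]
) -> list[float]:
    """Derive integer category upper bounds matching target group sizes.

    Given a vector of raw scores and the desired sizes of the first k-1
    groups (the last group takes the remainder), returns k-1 upper bounds
    chosen by rank so the realised groups approximate the targets — the
    mechanism for building score categories "similarly sized" to given
    mismatch-count groups on a new cohort.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    bounds: list[float] = []
    cum = 0
    for size in group_sizes:
        cum += int(size)
        if cum >= arr.size:
            raise ValueError("group sizes exceed the number of values")
        bounds.append(float(np.floor(arr[cum - 1])))
    return bounds


def spearman_correlation(
    x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
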