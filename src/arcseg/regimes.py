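"""Boundary extraction from a corrected arc curve and alert thresholds.

The regime-extracting procedure repeatedly takes the global minimum of the
curve and masks an exclusion zone of five subsequence lengths on each side,
so successive picks cannot be trivial neighbors of one another.  Alert
thresholds for negative-only training follow the statistical-process-control
heuristic: mean of the training minima minus three standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .segmentation import CorrectedArcCurve

__all__ = [
    "RegimeBoundaries",
    "AlertThreshold",
    "extract_regimes",
    "extract_regimes_by_count",
    "learn_threshold",
    "threshold_from_stats",
    "classify_snippet",
    "REA_EXCLUSION_FACTOR",
]

#: exclusion-zone half-width, in subsequence lengths, around each picked minimum.
REA_EXCLUSION_FACTOR = 5


@dataclass(frozen=True)
class RegimeBoundaries:
    """Ordered boundary positions with the curve values at which they were picked.

    ``exhausted`` is set when the curve ran out of admissible minima before
    ``num_requested`` boundaries were found.  ``cac_values`` is None for
    ground-truth boundary sets (no curve involved).
    """

    positions: np.ndarray
    cac_values: Optional[np.ndarray] = None
    num_requested: int = 0
    exhausted: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)
        if self.cac_values is not None:
            object.__setattr__(
                self, "cac_values", np.asarray(self.cac_values, dtype=np.float64)
            )

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class AlertThreshold:
    """mean - 3*std of negative-training minima, clipped to [0, 1]."""

    value: float
    train_mean: float
    train_std: float
    n_snippets: int


def extract_regimes(
    cac: "CorrectedArcCurve | np.ndarray", num_boundaries: int, L: int
) -> RegimeBoundaries:
    """Iteratively pick curve minima separated by an exclusion zone of 5L.

    Each round selects the global minimum of the working curve (ties break
    to the lowest index), records it, and masks ``REA_EXCLUSION_FACTOR * L``
    positions on each side.  If the curve is exhausted early, the boundaries
    found so far are returned with ``exhausted=True`` and a warning.
    """
    if num_boundaries < 1:
        raise ValueError("num_boundaries must be >= 1")
    if L < 1:
        raise ValueError("L must be positive")
    values = cac.values if isinstance(cac, CorrectedArcCurve) else np.asarray(cac, float)
    n = values.size
    if n <= 10 * L:
        raise ValueError(f"curve too short for extraction: need length > {10 * L}, got {n}")

    work = values.astype(np.float64).copy()
    zone = REA_EXCLUSION_FACTOR * L
    picks: list[int] = []
    vals: list[float] = []
    exhausted = False
    for _ in range(num_boundaries):
        pos = int(np.argmin(work))
        if not np.isfinite(work[pos]):
            exhausted = True
            break
        picks.append(pos)
        vals.append(float(values[pos]))
        work[max(0, pos - zone) : min(n, pos + zone + 1)] = np.inf
    if exhausted:
        warnings.warn(
            f"curve exhausted after {len(picks)} of {num_boundaries} boundaries",
            RuntimeWarning,
        )
    order = np.argsort(picks, kind="stable")
    return RegimeBoundaries(
        positions=np.asarray(picks, dtype=np.int64)[order],
        cac_values=np.asarray(vals, dtype=np.float64)[order],
        num_requested=num_boundaries,
        exhausted=exhausted,
    )


def extract_regimes_by_count(
    cac: "CorrectedArcCurve | np.ndarray", num_regimes: int, L: int
) -> RegimeBoundaries:
    """Convenience wrapper: ``num_regimes`` regimes have ``num_regimes - 1`` boundaries."""
    if num_regimes < 2:
        raise ValueError("num_regimes must be >= 2 (at least one boundary)")
    return extract_regimes(cac, num_regimes - 1, L)


def threshold_from_stats(mean: float, std: float, n_snippets: int = 0) -> AlertThreshold:
    """Alert threshold mean - 3*std from summary statistics, clipped to [0, 1]."""
    if std < 0:
        raise ValueError("std must be non-negative")
    value = float(np.clip(mean - 3.0 * std, 0.0, 1.0))
    return AlertThreshold(
        value=value, train_mean=float(mean), train_std=float(std), n_snippets=n_snippets
    )


def learn_threshold(min_cac_per_snippet: Sequence[float]) -> AlertThreshold:
    """Learn the alert threshold from per-snippet curve minima.

    Uses the population standard deviation (ddof=0); all-equal inputs give
    std 0 and a threshold equal to the mean.
    """
    x = np.asarray(min_cac_per_snippet, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least two training snippets")
    if not np.all(np.isfinite(x)):
        raise ValueError("training minima must be finite")
    return threshold_from_stats(float(x.mean()), float(x.std()), n_snippets=int(x.size))


def classify_snippet(
    cac: "CorrectedArcCurve | np.ndarray", threshold: AlertThreshold
) -> str:
    """``"regime_change"`` iff the curve minimum falls below the threshold.

    The alternative label is ``"no_evidence"`` — a high minimum is absence
    of evidence for a change, not evidence of absence.
    """
    values = cac.values if isinstance(cac, CorrectedArcCurve) else np.asarray(cac, float)
    return "regime_change" if float(values.min()) < threshold.value else "no_evidence"
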