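"""Robust aggregation of per-frame weight estimates from a walking sequence.

Single frames of a walking subject scatter widely (outliers beyond 30 % of
ground truth occur), but the good estimates cluster.  The aggregation ranks
every frame's estimate by its mean absolute distance to all other estimates,
keeps the tightest fraction (20 % by default) and returns the centroid of
the kept estimates.

The printed definition of the mean distance divides the sum of the N-1
absolute differences by N; the true mean over the summed terms divides by
N-1.  The ranking — and therefore the aggregate — is identical under either
convention; ``divisor`` selects one, defaulting to ``"N-1"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EstimationSeries", "mean_pairwise_distance", "select_core", "stream_estimate"]


@dataclass
class EstimationSeries:
    """Frame-ordered per-frame weight estimates (kg) for one subject."""

    estimates: np.ndarray
    person_id: int = 0

    def __post_init__(self) -> None:
        self.estimates = np.asarray(self.estimates, dtype=np.float64).reshape(-1)
        if len(self.estimates) < 1:
            raise ValueError("a series needs at least one estimate")
        if not np.all(np.isfinite(self.estimates)):
            raise ValueError("estimates must be finite")


def mean_pairwise_distance(w: np.ndarray, divisor: str = "N-1") -> np.ndarray:
    """Mean absolute distance of each estimate to all the others.

    ``d_i = (1/D) * sum_{j != i} |w_i - w_j|`` with ``D`` either ``N-1``
    (default; the true mean of the summed terms) or ``N`` (as printed in the
    aggregation rule's definition).
    """
    w = np.asarray(w, dtype=np.float64).reshape(-1)
    n = len(w)
    if n < 2:
        raise ValueError(f"need >= 2 estimates, got {n}")
    if divisor not in ("N", "N-1"):
        raise ValueError("divisor must be 'N' or 'N-1'")
    total = np.abs(w[:, None] - w[None, :]).sum(axis=1)
    return total / (n if divisor == "N" else n - 1)


def select_core(
    w: np.ndarray, d_bar: np.ndarray, keep_fraction: float = 0.2
) -> np.ndarray:
    """Indices of the ``max(1, round(keep_fraction * N))`` estimates with the
    smallest mean pairwise distance; ties go to the earlier frame."""
    w = np.asarray(w, dtype=np.float64).reshape(-1)
    d_bar = np.asarray(d_bar, dtype=np.float64).reshape(-1)
    if len(w) != len(d_bar):
        raise ValueError("w and d_bar must have equal length")
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError("keep_fraction must be in (0, 1]")
    n = len(w)
    n_keep = max(1, int(np.floor(keep_fraction * n + 0.5)))
    order = np.argsort(d_bar, kind="stable")  # stable: ties by frame order
    return np.sort(order[:n_keep])


def stream_estimate(
    series: EstimationSeries | np.ndarray,
    keep_fraction: float = 0.2,
    divisor: str = "N-1",
) -> float:
    """Aggregate a walking sequence into one weight estimate (kg).

    A single-frame series returns that frame's estimate unchanged.
    """
    w = series.estimates if isinstance(series, EstimationSeries) else np.asarray(
        series, dtype=np.float64
    ).reshape(-1)
    if len(w) == 0:
        raise ValueError("empty series")
    if len(w) == 1:
        return float(w[0])
    d_bar = mean_pairwise_distance(w, divisor=divisor)
    core = select_core(w, d_bar, keep_fraction)
    return float(w[core].mean())
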