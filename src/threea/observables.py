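"""Group-level order parameters and phase classification.

Polarization P is the norm of the mean heading; milling M is the norm of the
mean unit angular-momentum direction about the group centroid.  Both lie in
[0, 1].  Cohesion is summarized by the nearest-neighbor distance (NND).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .model import SchoolState

__all__ = [
    "OrderParameterSample",
    "OrderParameterSeries",
    "polarization",
    "milling",
    "nnd_stats",
    "classify_phase",
    "PHASE_LABELS",
]

PHASE_LABELS = ("fragmented", "swarming", "milling", "schooling")

_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class OrderParameterSample:
    time: float
    polarization: float
    milling: float
    nnd_mean: float
    nnd_sd: float


@dataclass
class OrderParameterSeries:
    """Time series of P, M and NND statistics for one run."""

    time: np.ndarray
    polarization: np.ndarray
    milling: np.ndarray
    nnd_mean: np.ndarray
    nnd_sd: np.ndarray

    def __len__(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time,
                "P": self.polarization,
                "M": self.milling,
                "nnd_mean": self.nnd_mean,
                "nnd_sd": self.nnd_sd,
            }
        )


def polarization(state: SchoolState) -> float:
    """P = |mean heading|: 1 for perfect alignment, ~N^-1/2 for random headings."""
    return float(np.linalg.norm(state.headings.mean(axis=0)))


def milling(state: SchoolState) -> float:
    """M = |mean of unit vectors (r_i - r_c) x p_i|: coherent group rotation.

    A fish exactly at the centroid, or heading parallel to its radial offset,
    has an undefined unit cross product; its contribution is the zero vector,
    which keeps M defined through symmetric configurations.
    """
    rel = state.positions - state.positions.mean(axis=0)
    cross = np.cross(rel, state.headings)
    norms = np.linalg.norm(cross, axis=1, keepdims=True)
    contrib = np.where(norms > _ZERO_TOL, cross / np.where(norms > _ZERO_TOL, norms, 1.0), 0.0)
    return float(np.linalg.norm(contrib.mean(axis=0)))


def nnd_stats(state: SchoolState) -> tuple[float, float]:
    """Mean and population standard deviation of each fish's nearest-neighbor
    distance (body lengths)."""
    if state.n_fish < 2:
        raise ValueError("nearest-neighbor distance needs at least 2 fish")
    dists = cdist(state.positions, state.positions)
    np.fill_diagonal(dists, np.inf)
    nnd = dists.min(axis=1)
    return float(nnd.mean()), float(nnd.std())


def classify_phase(
    p_mean: float,
    m_mean: float,
    nnd_mean: float,
    nnd_sd: float = 0.0,
    frag_nnd: float = 8.0,
    order_high: float = 0.65,
    order_low: float = 0.35,
) -> str:
    """Classify a steady-state ensemble point into one of the four phases.

    Fragmented when the mean NND exceeds ``frag_nnd`` (the school no longer
    holds together as one cohesive group); otherwise schooling when P is high
    and M low, milling when M is high and P low, and swarming when both order
    parameters are low.  The order-parameter cutoffs are a declared
    convention; the phases themselves are qualitatively well separated.
    """
    if nnd_mean > frag_nnd:
        return "fragmented"
    if p_mean >= order_high and m_mean < order_low:
        return "schooling"
    if m_mean >= order_high and p_mean < order_low:
        return "milling"
    return "swarming"
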