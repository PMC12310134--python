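"""Phenomenological transcritical SDE for the group polarization.

The milling-to-schooling transition is modelled by the normal form

    dP = r P (1 - P) dt + sigma dW,

where r is the distance from the bifurcation point (a proxy for zl - zl*)
and sigma the collective noise strength.  P = 0 (milling) and P = 1
(schooling) are equilibria for every r and exchange stability at r = 0: the
hallmark of a transcritical bifurcation.  The drift derives from the
effective potential U(P) = -r P^2 / 2 + r P^3 / 3 (dP = -U'(P) dt + ...),
which has |U(1) - U(0)| = r / 6 and U'' = -r, +r at P = 0, 1.

Paths are integrated with Euler-Maruyama; reflecting boundaries at 0 and 1
keep the order parameter in its physical range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SDEParams",
    "drift",
    "potential",
    "equilibria",
    "integrate_sde",
    "integrate_ensemble",
    "escape_times",
    "sde_hysteresis",
    "sde_hysteresis_loop",
    "loop_area",
    "SDEHysteresisResult",
]


@dataclass(frozen=True)
class SDEParams:
    r: float
    sigma: float
    p0: float = 0.0
    dt: float = 0.01
    total_time: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not 0 <= self.p0 <= 1:
            raise ValueError("p0 must be in [0, 1]")


def drift(p, r):
    """Deterministic drift r * p * (1 - p); vanishes at p = 0, 1 and at r = 0."""
    p = np.asarray(p, dtype=float)
    out = r * p * (1.0 - p)
    return float(out) if out.ndim == 0 else out


def potential(p, r):
    """Effective potential U(p) = -r p^2 / 2 + r p^3 / 3 with U(0) = 0.

    Defined by drift = -dU/dp, so U(1) - U(0) = -r/6 and the barrier
    magnitude between the two equilibria is |r|/6.
    """
    p = np.asarray(p, dtype=float)
    out = -r * p**2 / 2.0 + r * p**3 / 3.0
    return float(out) if out.ndim == 0 else out


def equilibria(r: float) -> list[tuple[float, str]]:
    """The two equilibria P = 0 (milling) and P = 1 (schooling) with their
    stability; they exchange stability at r = 0 (both neutral there)."""
    if r == 0:
        return [(0.0, "neutral"), (1.0, "neutral")]
    if r < 0:
        return [(0.0, "stable"), (1.0, "unstable")]
    return [(0.0, "unstable"), (1.0, "stable")]


def _reflect(p: np.ndarray) -> np.ndarray:
    """Reflecting boundaries at 0 and 1."""
    p = np.abs(p)
    p = np.where(p > 1.0, 2.0 - p, p)
    # a single reflection suffices unless the step exceeds the domain
    while np.any((p < 0.0) | (p > 1.0)):
        p = np.abs(p)
        p = np.where(p > 1.0, 2.0 - p, p)
    return p


def _em_step(
    p: np.ndarray, r: float, sigma: float, dt: float, rng: np.random.Generator
) -> np.ndarray:
    p = p + r * p * (1.0 - p) * dt + sigma * np.sqrt(dt) * rng.standard_normal(p.shape)
    return _reflect(p)


def integrate_sde(
    params: SDEParams, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama path of one polarization trajectory.

    Returns (times, P) including the initial condition; P stays in [0, 1].
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_steps = int(round(params.total_time / params.dt))
    path = np.empty(n_steps + 1)
    p = np.array([params.p0], dtype=float)
    path[0] = p[0]
    for k in range(1, n_steps + 1):
        p = _em_step(p, params.r, params.sigma, params.dt, rng)
        path[k] = p[0]
    times = params.dt * np.arange(n_steps + 1)
    return times, path


def integrate_ensemble(
    p0: np.ndarray,
    r: float,
    sigma: float,
    dt: float,
    n_steps: int,
    rng: np.random.Generator,
    record: bool = False,
):
    """Advance an ensemble of paths (vectorized over replicates).

    Returns the final ensemble, or the full (n_steps+1, n_paths) array when
    ``record`` is set.
    """
    p = np.array(p0, dtype=float)
    if record:
        out = np.empty((n_steps + 1, p.size))
        out[0] = p
        for k in range(1, n_steps + 1):
            p = _em_step(p, r, sigma, dt, rng)
            out[k] = p
        return out
    for _ in range(n_steps):
        p = _em_step(p, r, sigma, dt, rng)
    return p


def escape_times(
    r: float,
    sigma: float,
    n_paths: int,
    p0: float = 0.0,
    target: float = 0.9,
    dt: float = 0.01,
    t_max: float = 1000.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> np.ndarray:
    """First time each path reaches ``target`` starting from ``p0``.

    Vectorized Monte-Carlo first-passage times; paths that have not escaped
    by ``t_max`` are reported as NaN.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    p = np.full(n_paths, float(p0))
    times = np.full(n_paths, np.nan)
    active = np.ones(n_paths, dtype=bool)
    n_steps = int(round(t_max / dt))
    for k in range(1, n_steps + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        p[idx] = _em_step(p[idx], r, sigma, dt, rng)
        hit = idx[p[idx] >= target]
        if hit.size:
            times[hit] = k * dt
            active[hit] = False
    return times


@dataclass
class SDEHysteresisResult:
    """Trailing-window ensemble mean of P at each held value of r."""

    direction: str
    r_values: np.ndarray
    p_means: np.ndarray
    sigma: float
    per_replicate: pd.DataFrame | None = None


def sde_hysteresis(
    r_schedule,
    sigma: float,
    hold_time: float = 10.0,
    n_replicates: int = 50,
    dt: float = 0.01,
    window: float | None = None,
    p0: float | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    initial: np.ndarray | None = None,
    return_final: bool = False,
):
    """Quasi-static sweep of r with state continuity across schedule steps.

    Each of ``n_replicates`` paths evolves through the whole schedule; at each
    r the trailing ``window`` (default: hold_time / 5) of the hold is
    averaged.  ``initial`` seeds the ensemble (e.g. with the final ensemble of
    a forward sweep); otherwise all paths start at ``p0`` (default: the
    stable equilibrium of the first scheduled r).
    """
    r_schedule = np.asarray(r_schedule, dtype=float)
    if window is None:
        window = hold_time / 5.0
    if rng is None:
        rng = np.random.default_rng(seed)
    if initial is not None:
        p = np.array(initial, dtype=float)
    else:
        if p0 is None:
            p0 = 0.0 if r_schedule[0] <= 0 else 1.0
        p = np.full(n_replicates, float(p0))
    n_hold = int(round(hold_time / dt))
    n_window = max(1, int(round(window / dt)))
    p_means = np.empty(r_schedule.size)
    for j, r in enumerate(r_schedule):
        acc = np.zeros_like(p)
        for k in range(1, n_hold + 1):
            p = _em_step(p, r, sigma, dt, rng)
            if k > n_hold - n_window:
                acc += p
        p_means[j] = float((acc / n_window).mean())
    direction = "forward" if r_schedule[-1] >= r_schedule[0] else "backward"
    result = SDEHysteresisResult(
        direction=direction, r_values=r_schedule, p_means=p_means, sigma=sigma
    )
    if return_final:
        return result, p
    return result


def sde_hysteresis_loop(
    r_values,
    sigma: float,
    hold_time: float = 10.0,
    n_replicates: int = 50,
    dt: float = 0.01,
    window: float | None = None,
    seed: int = 0,
) -> tuple[SDEHysteresisResult, SDEHysteresisResult]:
    """Forward sweep over ``r_values`` then backward over the reversed
    schedule, with the forward final ensemble seeding the backward sweep."""
    r_values = np.asarray(r_values, dtype=float)
    rng = np.random.default_rng(seed)
    forward, final = sde_hysteresis(
        r_values, sigma, hold_time, n_replicates, dt, window, rng=rng,
        return_final=True,
    )
    backward = sde_hysteresis(
        r_values[::-1], sigma, hold_time, n_replicates, dt, window, rng=rng,
        initial=final,
    )
    return forward, backward


def loop_area(
    forward: SDEHysteresisResult, backward: SDEHysteresisResult
) -> float:
    """Area enclosed by the forward/backward P(r) loop (P * r units).

    Computed as |integral of (P_fwd - P_bwd) dr| over the common grid.  The
    signed integrand makes Monte-Carlo noise cancel; an absolute-value
    integrand would report a spurious positive area of order
    sd(P)/sqrt(n_replicates) even for perfectly reversible dynamics.
    """
    r = forward.r_values
    p_b = backward.p_means[::-1]
    if not np.allclose(backward.r_values[::-1], r):
        raise ValueError("forward and backward sweeps use different r grids")
    return float(abs(np.trapezoid(forward.p_means - p_b, r)))
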