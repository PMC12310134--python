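"""Monte-Carlo experiment drivers.

These protocols generate every ensemble the downstream analyses consume:
single runs with order-parameter recording, steady-state averages over a
trailing window, the (zl, za) phase diagram, the zl bifurcation sweep, and
the quasi-static hysteresis sweeps in which the final state at one parameter
value seeds the next (state continuity is the mechanism of collective
memory).

Seeding: replicate k at grid point i uses the stream seeded with
``base_seed + i * n_replicates + k``, so every (grid point, replicate) pair
is an independent, reproducible stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import SchoolState, init_state, step
from .observables import (
    OrderParameterSeries,
    classify_phase,
    milling,
    nnd_stats,
    polarization,
)
from .params import SimulationParams

__all__ = [
    "EnsembleSpec",
    "SweepResult",
    "HysteresisResult",
    "run_simulation",
    "steady_state_average",
    "phase_sweep",
    "bifurcation_sweep",
    "hysteresis_sweep",
    "hysteresis_loop",
    "estimate_crossing",
]


@dataclass(frozen=True)
class EnsembleSpec:
    """Ensemble settings shared by the sweep protocols."""

    base_params: SimulationParams
    n_replicates: int = 20
    averaging_window: float = 50.0  # trailing window for steady-state means
    record_every: float = 0.5  # observable output cadence

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.averaging_window > self.base_params.total_time:
            raise ValueError("averaging_window must not exceed total_time")


@dataclass
class SweepResult:
    """Per-parameter-value ensemble summaries for a sweep protocol."""

    parameter_values: list
    p_means: np.ndarray
    m_means: np.ndarray
    nnd_means: np.ndarray
    nnd_sds: np.ndarray
    schooling_fractions: np.ndarray
    milling_fractions: np.ndarray
    labels: list
    per_replicate: pd.DataFrame
    zl_star_grid: float | None = None
    zl_star_interp: float | None = None

    def summary_frame(self) -> pd.DataFrame:
        values = self.parameter_values
        if values and isinstance(values[0], tuple):
            cols = {"zl": [v[0] for v in values], "za": [v[1] for v in values]}
        else:
            cols = {"zl": list(values)}
        cols.update(
            P_mean=self.p_means,
            M_mean=self.m_means,
            nnd_mean=self.nnd_means,
            nnd_sd=self.nnd_sds,
            schooling_fraction=self.schooling_fractions,
            milling_fraction=self.milling_fractions,
            label=self.labels,
        )
        return pd.DataFrame(cols)


@dataclass
class HysteresisResult:
    """One direction of a quasi-static parameter sweep with state continuity."""

    direction: str  # "forward" or "backward"
    parameter_values: np.ndarray
    p_means: np.ndarray
    m_means: np.ndarray
    noise_sigma: float
    per_replicate: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "zl": self.parameter_values,
                "P_mean": self.p_means,
                "M_mean": self.m_means,
            }
        )


def _record_series(
    state: SchoolState,
    params: SimulationParams,
    rng: np.random.Generator,
    duration: float,
    record_every: float,
) -> tuple[OrderParameterSeries, SchoolState]:
    """Integrate ``state`` for ``duration``, recording observables at the given
    cadence (including the initial and final instants)."""
    n_steps = int(round(duration / params.dt))
    cadence = max(1, int(round(record_every / params.dt)))
    times, ps, ms, nnds, nndsds = [], [], [], [], []

    def _snap(s: SchoolState) -> None:
        times.append(s.time)
        ps.append(polarization(s))
        ms.append(milling(s))
        if s.n_fish >= 2:
            m, sd = nnd_stats(s)
        else:
            m, sd = np.nan, np.nan
        nnds.append(m)
        nndsds.append(sd)

    _snap(state)
    for k in range(1, n_steps + 1):
        state = step(state, params, rng)
        if k % cadence == 0 or k == n_steps:
            _snap(state)
    series = OrderParameterSeries(
        time=np.array(times),
        polarization=np.array(ps),
        milling=np.array(ms),
        nnd_mean=np.array(nnds),
        nnd_sd=np.array(nndsds),
    )
    return series, state


def run_simulation(
    params: SimulationParams,
    rng: np.random.Generator | None = None,
    record_every: float = 0.5,
    return_state: bool = False,
):
    """Integrate one school from a random initial condition for ``total_time``,
    recording order parameters every ``record_every`` time units."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = init_state(params, rng)
    series, final = _record_series(state, params, rng, params.total_time, record_every)
    if return_state:
        return series, final
    return series


def steady_state_average(
    series: OrderParameterSeries, window: float
) -> tuple[float, float, float, float]:
    """Unweighted means of (P, M, NND, sigma_NND) over samples with
    time > end - window."""
    if window <= 0:
        raise ValueError("window must be > 0")
    mask = series.time > series.time[-1] - window
    if not np.any(mask):
        raise ValueError("averaging window contains no samples")
    return (
        float(series.polarization[mask].mean()),
        float(series.milling[mask].mean()),
        float(series.nnd_mean[mask].mean()),
        float(series.nnd_sd[mask].mean()),
    )


def estimate_crossing(
    values: np.ndarray, fractions: np.ndarray, level: float = 0.5
) -> tuple[float | None, float | None]:
    """First grid value where ``fractions`` reaches ``level``, plus the linear
    interpolation between the bracketing grid points.

    Returns (None, None) when the level is never reached; the interpolated
    value falls back to the grid value when there is no bracketing point
    below the level.
    """
    values = np.asarray(values, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    above = np.flatnonzero(fractions >= level)
    if above.size == 0:
        return None, None
    i = int(above[0])
    grid = float(values[i])
    if i == 0 or fractions[i] == fractions[i - 1]:
        return grid, grid
    f0, f1 = fractions[i - 1], fractions[i]
    x0, x1 = values[i - 1], values[i]
    interp = float(x0 + (level - f0) * (x1 - x0) / (f1 - f0))
    return grid, interp


def _ensemble_point(
    spec: EnsembleSpec,
    params: SimulationParams,
    seed_offset: int,
    meta: dict,
) -> list[dict]:
    """Run the replicates of one grid point; one record per replicate."""
    records = []
    for k in range(spec.n_replicates):
        seed = spec.base_params.seed + seed_offset + k
        rng = np.random.default_rng(seed)
        series = run_simulation(params, rng, record_every=spec.record_every)
        pbar, mbar, nnd, nnd_sd = steady_state_average(series, spec.averaging_window)
        label = classify_phase(pbar, mbar, nnd, nnd_sd)
        records.append(
            dict(
                meta,
                replicate=k,
                seed=seed,
                P_mean=pbar,
                M_mean=mbar,
                nnd_mean=nnd,
                nnd_sd=nnd_sd,
                label=label,
            )
        )
    return records


def _aggregate(parameter_values: list, per_replicate: pd.DataFrame) -> SweepResult:
    groups = per_replicate.groupby("point", sort=True)
    agg = groups.agg(
        P_mean=("P_mean", "mean"),
        M_mean=("M_mean", "mean"),
        nnd_mean=("nnd_mean", "mean"),
        nnd_sd=("nnd_sd", "mean"),
    )
    school_frac = groups["label"].apply(lambda s: float((s == "schooling").mean()))
    mill_frac = groups["label"].apply(lambda s: float((s == "milling").mean()))
    labels = [
        classify_phase(
            agg["P_mean"].iloc[i],
            agg["M_mean"].iloc[i],
            agg["nnd_mean"].iloc[i],
            agg["nnd_sd"].iloc[i],
        )
        for i in range(len(agg))
    ]
    return SweepResult(
        parameter_values=parameter_values,
        p_means=agg["P_mean"].to_numpy(),
        m_means=agg["M_mean"].to_numpy(),
        nnd_means=agg["nnd_mean"].to_numpy(),
        nnd_sds=agg["nnd_sd"].to_numpy(),
        schooling_fractions=school_frac.to_numpy(),
        milling_fractions=mill_frac.to_numpy(),
        labels=labels,
        per_replicate=per_replicate.drop(columns=["point"]),
    )


def phase_sweep(
    spec: EnsembleSpec, zl_values, za_values
) -> SweepResult:
    """Ensemble sweep over the (zl, za) grid: steady-state means and a phase
    label per grid point."""
    points = [(float(zl), float(za)) for za in za_values for zl in zl_values]
    if not points:
        raise ValueError("empty (zl, za) grid")
    records: list[dict] = []
    for i, (zl, za) in enumerate(points):
        params = spec.base_params.replace(z_alignment=zl, z_attraction=za)
        records.extend(
            _ensemble_point(
                spec, params, i * spec.n_replicates, {"point": i, "zl": zl, "za": za}
            )
        )
    per_replicate = pd.DataFrame(records)
    return _aggregate(points, per_replicate)


def bifurcation_sweep(spec: EnsembleSpec, zl_values, za: float = 10.0) -> SweepResult:
    """Sweep zl at fixed za from random initial conditions.

    Reports per-zl ensemble means, the fraction of replicates whose steady
    state classifies as schooling (and milling), and the estimated transition
    point zl* where the schooling fraction first reaches one half (grid value
    and linear interpolation between the bracketing grid points).
    """
    zl_values = [float(z) for z in zl_values]
    if sorted(zl_values) != zl_values:
        raise ValueError("zl grid must be increasing")
    records: list[dict] = []
    for i, zl in enumerate(zl_values):
        params = spec.base_params.replace(z_alignment=zl, z_attraction=float(za))
        records.extend(
            _ensemble_point(
                spec, params, i * spec.n_replicates, {"point": i, "zl": zl}
            )
        )
    per_replicate = pd.DataFrame(records)
    result = _aggregate(zl_values, per_replicate)
    result.zl_star_grid, result.zl_star_interp = estimate_crossing(
        np.array(zl_values), result.schooling_fractions
    )
    return result


def hysteresis_sweep(
    spec: EnsembleSpec,
    zl_start: float = 1.0,
    zl_end: float = 5.0,
    dzl: float = 0.25,
    hold_time: float = 400.0,
    direction: str = "forward",
    za: float = 10.0,
    initial_states: list[SchoolState] | None = None,
    rngs: list[np.random.Generator] | None = None,
    return_final_states: bool = False,
):
    """Quasi-static zl sweep: at each value the school evolves for
    ``hold_time`` and its final state seeds the next value.

    ``direction`` "forward" sweeps zl_start -> zl_end (strictly increasing),
    "backward" sweeps zl_end -> zl_start.  Each replicate evolves
    independently through the whole schedule; for a backward sweep pass the
    forward replicates' final states as ``initial_states``.
    """
    if hold_time <= spec.averaging_window:
        raise ValueError("hold_time must exceed the averaging window")
    n_values = int(round((zl_end - zl_start) / dzl)) + 1
    forward_values = zl_start + dzl * np.arange(n_values)
    values = forward_values if direction == "forward" else forward_values[::-1]
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")

    n_rep = spec.n_replicates
    if rngs is None:
        offset = 0 if direction == "forward" else n_rep
        rngs = [
            np.random.default_rng(spec.base_params.seed + offset + k)
            for k in range(n_rep)
        ]
    p_acc = np.zeros((len(values), n_rep))
    m_acc = np.zeros((len(values), n_rep))
    finals: list[SchoolState] = []
    records: list[dict] = []
    for k in range(n_rep):
        rng = rngs[k]
        params = spec.base_params.replace(
            z_alignment=float(values[0]), z_attraction=float(za)
        )
        state = initial_states[k] if initial_states is not None else init_state(params, rng)
        for j, zl in enumerate(values):
            params = spec.base_params.replace(
                z_alignment=float(zl), z_attraction=float(za)
            )
            series, state = _record_series(
                state, params, rng, hold_time, spec.record_every
            )
            pbar, mbar, _, _ = steady_state_average(series, spec.averaging_window)
            p_acc[j, k] = pbar
            m_acc[j, k] = mbar
            records.append(
                dict(direction=direction, zl=float(zl), replicate=k, P_mean=pbar, M_mean=mbar)
            )
        finals.append(state)
    result = HysteresisResult(
        direction=direction,
        parameter_values=np.asarray(values, dtype=float),
        p_means=p_acc.mean(axis=1),
        m_means=m_acc.mean(axis=1),
        noise_sigma=spec.base_params.noise_sigma,
        per_replicate=pd.DataFrame(records),
    )
    if return_final_states:
        return result, finals
    return result


def hysteresis_loop(
    spec: EnsembleSpec,
    zl_start: float = 1.0,
    zl_end: float = 5.0,
    dzl: float = 0.25,
    hold_time: float = 400.0,
    za: float = 10.0,
) -> tuple[HysteresisResult, HysteresisResult]:
    """Forward sweep from random initial conditions, then backward sweep with
    each replicate restarted from its own forward endpoint state."""
    forward, finals = hysteresis_sweep(
        spec, zl_start, zl_end, dzl, hold_time, "forward", za,
        return_final_states=True,
    )
    backward = hysteresis_sweep(
        spec, zl_start, zl_end, dzl, hold_time, "backward", za,
        initial_states=finals,
    )
    return forward, backward
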