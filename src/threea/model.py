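"""Agent update rule of the zonal avoid/align/attract schooling model.

Each fish is a self-propelled particle at constant speed in 3D.  At every
step it computes a desired heading from neighbors in three nested zones —
repulsion (highest priority), alignment and attraction — restricted to its
field of view for the latter two, then Cartesian Gaussian noise is added to
the desired heading, the turn is clamped against the current heading (the
turning constraint is a rate: at most ``max_turn * dt`` degrees per step),
and the position advances along the new heading.

The update is synchronous: all desired headings are computed from the state
at time t before any fish moves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .params import SimulationParams

__all__ = [
    "SchoolState",
    "NeighborPartition",
    "init_state",
    "in_field_of_view",
    "partition_neighbors",
    "desired_heading",
    "apply_rotational_noise",
    "clamp_turn",
    "step",
]

_ZERO_TOL = 1e-12
# relative slack on the cos(alpha/2) comparison so the angular boundary
# alpha/2 itself counts as visible despite rounding
_FOV_TOL = 1e-12


@dataclass
class SchoolState:
    """Positions and unit headings of all N fish at one instant."""

    time: float
    positions: np.ndarray  # (N, 3) body lengths
    headings: np.ndarray  # (N, 3) unit vectors

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.headings = np.asarray(self.headings, dtype=float)
        if self.positions.shape != self.headings.shape or self.positions.ndim != 2:
            raise ValueError("positions and headings must both have shape (N, 3)")
        if self.positions.shape[1] != 3:
            raise ValueError("state vectors must be three-dimensional")
        sq = np.einsum("ij,ij->i", self.headings, self.headings)
        if float(np.abs(sq - 1.0).max(initial=0.0)) > 2.1e-9:  # |n^2-1| ~ 2|n-1|
            raise ValueError("headings must be unit vectors (|p| = 1 within 1e-9)")

    @property
    def n_fish(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class NeighborPartition:
    """Indices of one fish's neighbors in the repulsion/alignment/attraction zones."""

    repulsion_ids: tuple = field(default_factory=tuple)
    alignment_ids: tuple = field(default_factory=tuple)
    attraction_ids: tuple = field(default_factory=tuple)


def init_state(params: SimulationParams, rng: np.random.Generator) -> SchoolState:
    """Random initial condition: positions i.i.d. uniform in the unit cube,
    headings i.i.d. uniform on the unit sphere."""
    positions = rng.uniform(0.0, 1.0, size=(params.n_fish, 3))
    raw = rng.standard_normal(size=(params.n_fish, 3))
    norms = np.linalg.norm(raw, axis=1, keepdims=True)
    # standard-normal triples of zero norm have probability zero; guard anyway
    while np.any(norms < _ZERO_TOL):
        bad = norms[:, 0] < _ZERO_TOL
        raw[bad] = rng.standard_normal(size=(int(bad.sum()), 3))
        norms = np.linalg.norm(raw, axis=1, keepdims=True)
    return SchoolState(time=0.0, positions=positions, headings=raw / norms)


def in_field_of_view(
    heading: np.ndarray, offset: np.ndarray, field_of_view: float
) -> bool:
    """Whether a neighbor at ``offset`` from the focal fish is visible.

    Visible iff the angle between the heading and the offset is <= alpha/2;
    the blind cone of angle 360 - alpha lies directly behind the heading.
    The boundary angle alpha/2 counts as visible.
    """
    offset = np.asarray(offset, dtype=float)
    dist = np.linalg.norm(offset)
    if dist < _ZERO_TOL:
        raise ValueError("zero offset: two fish occupy the same position")
    cos_half = np.cos(np.radians(field_of_view) / 2.0)
    return bool(np.dot(heading, offset) >= (cos_half - _FOV_TOL) * dist)


def _distances(positions: np.ndarray) -> np.ndarray:
    """Pairwise distances with +inf on the diagonal; errors on coincidence."""
    dists = cdist(positions, positions)
    np.fill_diagonal(dists, np.inf)
    if dists.min() < _ZERO_TOL:
        raise ValueError("coincident fish positions: pairwise distance is zero")
    return dists


def _zone_masks(state: SchoolState, params: SimulationParams):
    """Boolean (N, N) masks rep/align/attr; entry [i, j] marks j as a zone
    neighbor of focal fish i."""
    dists = _distances(state.positions)
    cos_half = np.cos(np.radians(params.field_of_view) / 2.0)
    # dots[i, j] = p_i . (r_j - r_i), via one BLAS product
    proj = state.headings @ state.positions.T
    dots = proj - np.einsum("ij,ij->i", state.headings, state.positions)[:, None]
    visible = dots >= (cos_half - _FOV_TOL) * dists
    rep = dists <= params.z_repulsion
    if params.vision_filters_repulsion:
        rep &= visible
    align = (dists > params.z_repulsion) & (dists <= params.z_alignment) & visible
    attr = (dists > params.z_alignment) & (dists <= params.z_attraction) & visible
    return dists, rep, align, attr


def partition_neighbors(
    state: SchoolState, focal: int, params: SimulationParams
) -> NeighborPartition:
    """Zone membership of every neighbor of ``focal``.

    The repulsion zone uses distance only; the alignment and attraction
    shells additionally require the neighbor to be inside the field of view.
    """
    if not 0 <= focal < state.n_fish:
        raise IndexError(f"focal index {focal} out of range for N={state.n_fish}")
    _, rep, align, attr = _zone_masks(state, params)
    return NeighborPartition(
        repulsion_ids=tuple(np.flatnonzero(rep[focal])),
        alignment_ids=tuple(np.flatnonzero(align[focal])),
        attraction_ids=tuple(np.flatnonzero(attr[focal])),
    )


def _unit_rows(vectors: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    """Row-normalize; rows with (near-)zero norm are replaced by ``fallback``."""
    norms = np.sqrt(np.einsum("ij,ij->i", vectors, vectors))[:, None]
    safe = np.where(norms > _ZERO_TOL, norms, 1.0)
    out = vectors / safe
    zero = norms[:, 0] <= _ZERO_TOL
    if np.any(zero):
        out[zero] = fallback[zero]
    return out


def _weighted_offset_sum(weights: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """sum_j w[i, j] * (r_j - r_i) as two BLAS products (no N x N x 3 tensor)."""
    return weights @ positions - weights.sum(axis=1)[:, None] * positions


def _desired_headings(state: SchoolState, params: SimulationParams) -> np.ndarray:
    """Noise-free desired headings of all fish (synchronous, vectorized).

    Repulsion has absolute priority: a fish with any repulsion-zone neighbor
    steers along the negative mean of the unit vectors toward them.  Otherwise
    it averages a unit alignment consensus and a unit attraction direction,
    dropping whichever term has no neighbors.  A zero resultant (or no
    neighbors at all) leaves the current heading unchanged.
    """
    dists, rep, align, attr = _zone_masks(state, params)
    inv_d = 1.0 / dists  # diagonal: 1/inf = 0
    current = state.headings
    positions = state.positions

    # sum over zone of unit vectors rhat_ij = (r_j - r_i) / d_ij
    rep_vec = -_weighted_offset_sum(rep * inv_d, positions)
    rep_dir = _unit_rows(rep_vec, current)

    align_dir = _unit_rows(align.astype(float) @ current, np.zeros_like(current))
    attr_dir = _unit_rows(_weighted_offset_sum(attr * inv_d, positions),
                          np.zeros_like(current))
    social = _unit_rows(align_dir + attr_dir, current)
    # fish with no alignment/attraction neighbors at all keep their heading
    lonely = ~(align.any(axis=1) | attr.any(axis=1))
    if np.any(lonely):
        social[lonely] = current[lonely]

    has_rep = rep.any(axis=1)
    return np.where(has_rep[:, None], rep_dir, social)


def desired_heading(
    state: SchoolState, focal: int, params: SimulationParams
) -> np.ndarray:
    """Noise-free desired heading of one fish (see ``_desired_headings``)."""
    if not 0 <= focal < state.n_fish:
        raise IndexError(f"focal index {focal} out of range for N={state.n_fish}")
    return _desired_headings(state, params)[focal]


def apply_rotational_noise(
    heading: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Perturb a unit heading by i.i.d. Gaussian(0, sigma^2) per component and
    renormalize (spherically wrapped Gaussian about the heading)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    heading = np.asarray(heading, dtype=float)
    if sigma == 0:
        return heading.copy()
    vec = heading + sigma * rng.standard_normal(3)
    norm = np.linalg.norm(vec)
    while norm < _ZERO_TOL:  # probability zero; resample
        vec = heading + sigma * rng.standard_normal(3)
        norm = np.linalg.norm(vec)
    return vec / norm


def _apply_noise_all(
    headings: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized noise for all fish; draws are made in fish-index order."""
    if sigma == 0:
        return headings
    vec = headings + sigma * rng.standard_normal(headings.shape)
    norms = np.linalg.norm(vec, axis=1, keepdims=True)
    while np.any(norms < _ZERO_TOL):
        bad = norms[:, 0] < _ZERO_TOL
        vec[bad] = headings[bad] + sigma * rng.standard_normal((int(bad.sum()), 3))
        norms = np.linalg.norm(vec, axis=1, keepdims=True)
    return vec / norms


def _fixed_perpendicular(v: np.ndarray) -> np.ndarray:
    """Deterministic unit vector perpendicular to v (rng-free tie-break for
    antiparallel turns): cross v with the coordinate axis it is least aligned
    with."""
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(v)))] = 1.0
    perp = np.cross(v, axis)
    return perp / np.linalg.norm(perp)


def clamp_turn(
    current: np.ndarray, desired: np.ndarray, max_turn: float
) -> np.ndarray:
    """Limit the turn from ``current`` toward ``desired`` to ``max_turn`` degrees.

    If the angle between them exceeds the limit, the fish rotates by exactly
    ``max_turn`` within the plane spanned by the two headings.  When they are
    antiparallel the rotation plane is undefined; a fixed perpendicular axis
    (deterministic, rng-free) is used.
    """
    current = np.asarray(current, dtype=float)
    desired = np.asarray(desired, dtype=float)
    cosang = float(np.clip(np.dot(current, desired), -1.0, 1.0))
    angle = np.degrees(np.arccos(cosang))
    if angle <= max_turn + 1e-9:
        return desired.copy()
    # unit component of desired perpendicular to current
    perp = desired - cosang * current
    norm = np.linalg.norm(perp)
    u = _fixed_perpendicular(current) if norm < _ZERO_TOL else perp / norm
    theta = np.radians(max_turn)
    out = np.cos(theta) * current + np.sin(theta) * u
    return out / np.linalg.norm(out)


def _clamp_turn_all(
    current: np.ndarray, desired: np.ndarray, max_turn: float
) -> np.ndarray:
    """Vectorized ``clamp_turn`` over all fish."""
    cosang = np.clip(np.einsum("ik,ik->i", current, desired), -1.0, 1.0)
    over = np.degrees(np.arccos(cosang)) > max_turn + 1e-9
    if not np.any(over):
        return desired
    out = desired.copy()
    cur = current[over]
    perp = desired[over] - cosang[over, None] * cur
    norms = np.linalg.norm(perp, axis=1, keepdims=True)
    degenerate = norms[:, 0] < _ZERO_TOL
    u = np.empty_like(perp)
    u[~degenerate] = perp[~degenerate] / norms[~degenerate]
    for i in np.flatnonzero(degenerate):  # antiparallel: rare
        u[i] = _fixed_perpendicular(cur[i])
    theta = np.radians(max_turn)
    rot = np.cos(theta) * cur + np.sin(theta) * u
    out[over] = rot / np.linalg.norm(rot, axis=1, keepdims=True)
    return out


try:  # optional acceleration; the numpy path below is the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

if _HAVE_NUMBA:

    @_njit(cache=False)
    def _desired_kernel(positions, headings, zr, zl, za, cos_half, vision_rep):
        n = positions.shape[0]
        desired = np.empty((n, 3))
        za2 = za * za
        for i in range(n):
            rx = ry = rz = 0.0
            alx = aly = alz = 0.0
            atx = aty = atz = 0.0
            n_rep = n_align = n_attr = 0
            pix, piy, piz = headings[i, 0], headings[i, 1], headings[i, 2]
            xi, yi, zi = positions[i, 0], positions[i, 1], positions[i, 2]
            for j in range(n):
                if j == i:
                    continue
                dx = positions[j, 0] - xi
                dy = positions[j, 1] - yi
                dz = positions[j, 2] - zi
                d2 = dx * dx + dy * dy + dz * dz
                if d2 > za2:
                    continue
                d = np.sqrt(d2)
                if d < _ZERO_TOL:
                    raise ValueError(
                        "coincident fish positions: pairwise distance is zero"
                    )
                visible = pix * dx + piy * dy + piz * dz >= (cos_half - _FOV_TOL) * d
                if d <= zr:
                    if vision_rep and not visible:
                        continue
                    n_rep += 1
                    rx += dx / d
                    ry += dy / d
                    rz += dz / d
                elif visible and d <= zl:
                    n_align += 1
                    alx += headings[j, 0]
                    aly += headings[j, 1]
                    alz += headings[j, 2]
                elif visible:
                    n_attr += 1
                    atx += dx / d
                    aty += dy / d
                    atz += dz / d
            if n_rep > 0:
                vx, vy, vz = -rx, -ry, -rz
            else:
                vx = vy = vz = 0.0
                if n_align > 0:
                    nrm = np.sqrt(alx * alx + aly * aly + alz * alz)
                    if nrm > _ZERO_TOL:
                        vx += alx / nrm
                        vy += aly / nrm
                        vz += alz / nrm
                if n_attr > 0:
                    nrm = np.sqrt(atx * atx + aty * aty + atz * atz)
                    if nrm > _ZERO_TOL:
                        vx += atx / nrm
                        vy += aty / nrm
                        vz += atz / nrm
            nrm = np.sqrt(vx * vx + vy * vy + vz * vz)
            if nrm > _ZERO_TOL:
                desired[i, 0] = vx / nrm
                desired[i, 1] = vy / nrm
                desired[i, 2] = vz / nrm
            else:  # zero resultant or no neighbors: keep current heading
                desired[i, 0] = pix
                desired[i, 1] = piy
                desired[i, 2] = piz
        return desired

    @_njit(cache=False)
    def _clamp_kernel(current, desired, max_turn_deg):
        n = current.shape[0]
        out = np.empty_like(desired)
        theta = np.radians(max_turn_deg)
        cos_lim = np.cos(theta)
        ct, st = np.cos(theta), np.sin(theta)
        for i in range(n):
            cx, cy, cz = current[i, 0], current[i, 1], current[i, 2]
            dx, dy, dz = desired[i, 0], desired[i, 1], desired[i, 2]
            dot = cx * dx + cy * dy + cz * dz
            if dot > 1.0:
                dot = 1.0
            elif dot < -1.0:
                dot = -1.0
            if np.degrees(np.arccos(dot)) <= max_turn_deg + 1e-9:
                out[i, 0] = dx
                out[i, 1] = dy
                out[i, 2] = dz
                continue
            ux = dx - dot * cx
            uy = dy - dot * cy
            uz = dz - dot * cz
            nrm = np.sqrt(ux * ux + uy * uy + uz * uz)
            if nrm < _ZERO_TOL:
                # antiparallel: deterministic perpendicular axis
                ax = np.abs(cx)
                ay = np.abs(cy)
                az = np.abs(cz)
                # cross(current, least-aligned axis), matching _fixed_perpendicular
                if ax <= ay and ax <= az:
                    ux, uy, uz = 0.0, cz, -cy
                elif ay <= az:
                    ux, uy, uz = -cz, 0.0, cx
                else:
                    ux, uy, uz = cy, -cx, 0.0
                nrm = np.sqrt(ux * ux + uy * uy + uz * uz)
            ux, uy, uz = ux / nrm, uy / nrm, uz / nrm
            ox = ct * cx + st * ux
            oy = ct * cy + st * uy
            oz = ct * cz + st * uz
            nrm = np.sqrt(ox * ox + oy * oy + oz * oz)
            out[i, 0] = ox / nrm
            out[i, 1] = oy / nrm
            out[i, 2] = oz / nrm
        return out


#: use the compiled kernels when numba is importable (the numpy implementation
#: is the reference; tests assert both paths agree)
USE_NUMBA = _HAVE_NUMBA


def step(
    state: SchoolState, params: SimulationParams, rng: np.random.Generator
) -> SchoolState:
    """Advance the whole school by one time step dt.

    Order of operations per fish: noise is applied to the noise-free desired
    heading, the resulting turn is clamped to ``max_turn * dt`` degrees
    against the heading at time t, and the position advances by U * dt along
    the *new* heading.
    """
    clamp_deg = params.max_turn_per_step
    if USE_NUMBA:
        desired = _desired_kernel(
            state.positions,
            state.headings,
            params.z_repulsion,
            params.z_alignment,
            params.z_attraction,
            np.cos(np.radians(params.field_of_view) / 2.0),
            params.vision_filters_repulsion,
        )
    else:
        desired = _desired_headings(state, params)
    noisy = _apply_noise_all(desired, params.noise_sigma, rng)
    if USE_NUMBA:
        new_headings = _clamp_kernel(state.headings, noisy, clamp_deg)
    else:
        new_headings = _clamp_turn_all(state.headings, noisy, clamp_deg)
    new_positions = state.positions + params.speed * params.dt * new_headings
    return SchoolState(
        time=state.time + params.dt,
        positions=new_positions,
        headings=new_headings,
    )


def iterate_states(params: SimulationParams, rng: np.random.Generator):
    """Yield the initial state followed by each stepped state."""
    state = init_state(params, rng)
    yield state
    for _ in range(params.n_steps):
        state = step(state, params, rng)
        yield state
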