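"""Individual-level model parameters and validation.

All lengths are in body lengths (the repulsion radius ``z_repulsion`` sets the
unit), time in "time units", and speed in body lengths per time unit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

__all__ = ["SimulationParams"]


@dataclass(frozen=True)
class SimulationParams:
    """Constants of the zonal avoid/align/attract model plus integration controls.

    Parameters
    ----------
    n_fish
        Number of individuals N.
    speed
        Constant swimming speed U (body lengths per time unit).
    z_repulsion, z_alignment, z_attraction
        Radii zr <= zl <= za of the nested spherical interaction zones
        (body lengths).  The repulsion zone is a ball of radius zr; the
        alignment and attraction zones are the shells (zr, zl] and (zl, za].
    field_of_view
        Angular size alpha of the visual field (degrees).  A blind cone of
        angle 360 - alpha lies directly behind the heading; neighbors inside
        it are invisible to the alignment and attraction rules.
    max_turn
        Maximum turning rate theta_max (degrees per time unit).  The heading
        update at each step is clamped to ``max_turn * dt`` degrees.
    noise_sigma
        Standard deviation sigma of the Cartesian heading noise added to each
        component of the desired heading before renormalization.
    dt
        Integration time step (time units).
    total_time
        Total simulated duration T (time units).
    seed
        Base seed for the random stream.
    vision_filters_repulsion
        Whether the blind cone also hides repulsion-zone neighbors.  The
        model's repulsion rule is distance-only by default.
    """

    n_fish: int = 100
    speed: float = 3.0
    z_repulsion: float = 1.0
    z_alignment: float = 2.0
    z_attraction: float = 10.0
    field_of_view: float = 270.0
    max_turn: float = 40.0
    noise_sigma: float = 0.01
    dt: float = 0.1
    total_time: float = 500.0
    seed: int = 0
    vision_filters_repulsion: bool = False

    def __post_init__(self) -> None:
        if self.n_fish < 1:
            raise ValueError(f"n_fish must be >= 1, got {self.n_fish}")
        if self.speed <= 0:
            raise ValueError(f"speed must be > 0, got {self.speed}")
        if not (0 < self.z_repulsion <= self.z_alignment <= self.z_attraction):
            raise ValueError(
                "zone radii must satisfy 0 < z_repulsion <= z_alignment <= "
                f"z_attraction, got zr={self.z_repulsion}, "
                f"zl={self.z_alignment}, za={self.z_attraction}"
            )
        if not (0 < self.field_of_view <= 360):
            raise ValueError(
                f"field_of_view must be in (0, 360], got {self.field_of_view}"
            )
        if self.max_turn <= 0:
            raise ValueError(f"max_turn must be > 0, got {self.max_turn}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.total_time <= 0:
            raise ValueError(f"total_time must be > 0, got {self.total_time}")

    def replace(self, **changes) -> "SimulationParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    @property
    def n_steps(self) -> int:
        return int(round(self.total_time / self.dt))

    @property
    def max_turn_per_step(self) -> float:
        """Per-step clamp angle in degrees (capped at 180)."""
        return min(self.max_turn * self.dt, 180.0)
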