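"""Cell-body translocation driven by the leading protrusion.

Only the longest protrusion adheres; its actomyosin retraction exerts a
traction F_trac = -alpha_adhesion * p on the ECM, whose reaction on the cell
body is balanced instantaneously by Stokes drag through the fluid phase of
the matrix:

    -6 pi r eta v + alpha_adhesion * p_lp = 0

so v = alpha_adhesion * p_lp / (6 pi r eta), directed along the leading
protrusion.  With alpha_adhesion in pN/um, r in um and eta in Pa s the ratio
comes out directly in um/s (1 Pa = 1 pN/um^2); velocities are reported in
um/min.  Position is advanced by explicit Euler at the 5-min mechanical
cadence — velocity is piecewise constant between mechanical steps, so a
higher-order integrator would add nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protrusions import Protrusion

__all__ = [
    "CellBody",
    "MotionParams",
    "longest_protrusion",
    "velocity_from_balance",
    "drag_force_pN",
    "traction_force_pN",
    "step_position",
]


@dataclass
class CellBody:
    """Cell centre position (mm), radius (um) and current velocity (um/min)."""

    position_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius_um: float = 10.0
    velocity_um_min: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.position_mm = np.asarray(self.position_mm, dtype=float)
        self.velocity_um_min = np.asarray(self.velocity_um_min, dtype=float)
        if self.radius_um <= 0:
            raise ValueError("cell radius must be > 0")


@dataclass(frozen=True)
class MotionParams:
    """ECM viscosity (Pa s) and adhesion traction coefficient (pN per um of length)."""

    eta_Pa_s: float = 7.5
    alpha_adhesion_pN_per_um: float = 1.0

    def __post_init__(self) -> None:
        if self.eta_Pa_s <= 0:
            raise ValueError("viscosity must be > 0")
        if self.alpha_adhesion_pN_per_um < 0:
            raise ValueError("adhesion coefficient must be >= 0")


def longest_protrusion(protrusions: list[Protrusion]) -> Protrusion | None:
    """The leading (maximal-length, live) protrusion.

    Ties are broken by earliest birth time, then lowest id; returns None if
    no protrusion is alive.
    """
    live = [p for p in protrusions if p.alive]
    if not live:
        return None
    return min(live, key=lambda p: (-p.length_um, p.birth_time_min, p.id))


def traction_force_pN(leading: Protrusion, params: MotionParams) -> np.ndarray:
    """Reaction force on the cell body from the leading protrusion (pN)."""
    return params.alpha_adhesion_pN_per_um * leading.length_um * leading.direction


def drag_force_pN(cell: CellBody, velocity_um_min: np.ndarray, params: MotionParams) -> np.ndarray:
    """Stokes drag -6 pi r eta v on the cell body (pN), v in um/min."""
    v_um_s = np.asarray(velocity_um_min, dtype=float) / 60.0
    return -6.0 * np.pi * cell.radius_um * params.eta_Pa_s * v_um_s


def velocity_from_balance(
    leading: Protrusion | None, params: MotionParams, cell: CellBody
) -> np.ndarray:
    """Velocity (um/min) from the drag/traction force balance; zero if no leader."""
    if leading is None or leading.length_um == 0.0:
        return np.zeros(3)
    speed_um_s = (
        params.alpha_adhesion_pN_per_um
        * leading.length_um
        / (6.0 * np.pi * cell.radius_um * params.eta_Pa_s)
    )
    return 60.0 * speed_um_s * leading.direction


def step_position(cell: CellBody, velocity_um_min: np.ndarray, dt_min: float = 5.0) -> CellBody:
    """Explicit-Euler position update over one mechanical step."""
    if dt_min <= 0:
        raise ValueError("dt must be > 0")
    v = np.asarray(velocity_um_min, dtype=float)
    cell.position_mm = cell.position_mm + v * dt_min * 1e-3
    cell.velocity_um_min = v.copy()
    return cell
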