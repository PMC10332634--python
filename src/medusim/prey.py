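"""Prey concentration field: advection-diffusion coupled to the flow.

The concentration ``F`` is stored at cell centers in units of the
saturation level ``F_0`` (so values live in roughly [0, 1]) and evolves by

    dF/dt + div(U F) = D_F laplace(F),      D_F = 0.001 m^2 s^-1

with no-flux walls.  Advective fluxes use a van Leer slope-limited MUSCL
reconstruction on the staggered face velocities and diffusive fluxes plain
central differences; both are written in conservative flux form, so total
prey is conserved to round-off and the scheme is positivity preserving at
the stability-bounded time step.  Time stepping is two-stage Heun (SSP-RK2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fluid import FlowField
from .geometry import TankGeometry

#: default prey diffusivity [m^2 s^-1]
DEFAULT_DIFFUSIVITY = 0.001

#: prey-gradient magnitude below which the prey direction is degenerate
GRADIENT_EPS = 1e-8


class StabilityError(RuntimeError):
    pass


@dataclass
class PreyField:
    """Scalar prey concentration on cell centers (units of F_0)."""

    geometry: TankGeometry
    F: np.ndarray                      # shape (nx-1, ny-1)
    diffusivity: float = DEFAULT_DIFFUSIVITY

    @classmethod
    def zeros(cls, geometry: TankGeometry, diffusivity: float = DEFAULT_DIFFUSIVITY) -> "PreyField":
        return cls(geometry, np.zeros((geometry.nx - 1, geometry.ny - 1)), diffusivity)

    def copy(self) -> "PreyField":
        return PreyField(self.geometry, self.F.copy(), self.diffusivity)

    def total_mass(self) -> float:
        g = self.geometry
        return float(self.F.sum() * g.dx * g.dy)

    def gradient(self):
        """(dF/dx, dF/dy) at cell centers; central inside, one-sided at walls."""
        g = self.geometry
        F = self.F
        gx = np.empty_like(F)
        gx[1:-1, :] = (F[2:, :] - F[:-2, :]) / (2 * g.dx)
        gx[0, :] = (F[1, :] - F[0, :]) / g.dx
        gx[-1, :] = (F[-1, :] - F[-2, :]) / g.dx
        gy = np.empty_like(F)
        gy[:, 1:-1] = (F[:, 2:] - F[:, :-2]) / (2 * g.dy)
        gy[:, 0] = (F[:, 1] - F[:, 0]) / g.dy
        gy[:, -1] = (F[:, -1] - F[:, -2]) / g.dy
        return gx, gy

    def stable_dt(self, flow: FlowField | None = None) -> float:
        """Largest stable explicit step (advective CFL 0.5, diffusive 0.25)."""
        g = self.geometry
        dt_diff = 0.25 / (self.diffusivity * (1.0 / g.dx**2 + 1.0 / g.dy**2))
        if flow is None:
            return dt_diff
        umax = max(flow.max_speed(), 1e-12)
        dt_adv = 0.5 * min(g.dx, g.dy) / umax
        return min(dt_diff, dt_adv)


def _van_leer(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """van Leer limited slope of neighbouring increments a, b."""
    prod = a * b
    denom = a + b
    out = np.zeros_like(a)
    mask = prod > 0
    out[mask] = 2.0 * prod[mask] / denom[mask]
    return out


def _tendency(F: np.ndarray, flow: FlowField, diffusivity: float) -> np.ndarray:
    """Conservative advection-diffusion tendency with no-flux walls."""
    g = flow.geometry
    dx, dy = g.dx, g.dy
    # ghost cells: zero-gradient (no-flux walls)
    Fp = np.pad(F, 2, mode="edge")

    # limited slopes per cell, on the twice-padded array interior
    sx = _van_leer(Fp[1:-1, 2:-2] - Fp[:-2, 2:-2], Fp[2:, 2:-2] - Fp[1:-1, 2:-2])
    sy = _van_leer(Fp[2:-2, 1:-1] - Fp[2:-2, :-2], Fp[2:-2, 2:] - Fp[2:-2, 1:-1])
    Fc_x = Fp[1:-1, 2:-2]   # cells padded by one in x
    Fc_y = Fp[2:-2, 1:-1]

    # x faces: interior faces i = 1..ncx-1 plus wall faces (flux forced 0)
    uf = flow.u  # (nx, ncy)
    # upwind reconstruction at all interior x faces
    left = Fc_x[:-1, :] + 0.5 * sx[:-1, :]     # from cell on the -x side
    right = Fc_x[1:, :] - 0.5 * sx[1:, :]      # from cell on the +x side
    face_F = np.where(uf > 0, left, right)
    flux_x = uf * face_F - diffusivity * (Fc_x[1:, :] - Fc_x[:-1, :]) / dx
    flux_x[0, :] = 0.0
    flux_x[-1, :] = 0.0

    vf = flow.v  # (ncx, ny)
    lo = Fc_y[:, :-1] + 0.5 * sy[:, :-1]
    hi = Fc_y[:, 1:] - 0.5 * sy[:, 1:]
    face_Fy = np.where(vf > 0, lo, hi)
    flux_y = vf * face_Fy - diffusivity * (Fc_y[:, 1:] - Fc_y[:, :-1]) / dy
    flux_y[:, 0] = 0.0
    flux_y[:, -1] = 0.0

    return -(flux_x[1:, :] - flux_x[:-1, :]) / dx - (flux_y[:, 1:] - flux_y[:, :-1]) / dy


def step_prey(prey: PreyField, flow: FlowField, dt: float) -> PreyField:
    """One Heun (SSP-RK2) advection-diffusion step, in place.

    Raises :class:`StabilityError` naming the binding constraint when dt
    exceeds the explicit stability bound.
    """
    g = prey.geometry
    dt_diff = 0.25 / (prey.diffusivity * (1.0 / g.dx**2 + 1.0 / g.dy**2)) if prey.diffusivity > 0 else np.inf
    umax = flow.max_speed()
    dt_adv = 0.5 * min(g.dx, g.dy) / umax if umax > 0 else np.inf
    if dt > dt_diff and dt_diff <= dt_adv:
        raise StabilityError(f"dt={dt:g}s exceeds diffusive stability bound {dt_diff:g}s")
    if dt > dt_adv:
        raise StabilityError(f"dt={dt:g}s exceeds advective CFL bound {dt_adv:g}s")
    F0 = prey.F
    k1 = _tendency(F0, flow, prey.diffusivity)
    F1 = F0 + dt * k1
    k2 = _tendency(F1, flow, prey.diffusivity)
    prey.F = F0 + 0.5 * dt * (k1 + k2)
    return prey


def init_double_gyre_prey(geometry: TankGeometry, diffusivity: float = DEFAULT_DIFFUSIVITY) -> PreyField:
    """Prey at saturation in the left gyre (x < 0), none on the right.

    The step is smoothed over ~2 cells with a tanh ramp to avoid dispersive
    ringing of the advection scheme.
    """
    if geometry.scenario != "double_gyre":
        raise ValueError("double-gyre prey initialisation requires the double_gyre scenario")
    xc = geometry.x_centers[:, None]
    F = 0.5 * (1.0 - np.tanh(xc / geometry.dx)) * np.ones((1, geometry.ny - 1))
    return PreyField(geometry, F, diffusivity)


def init_gaussian_blob(geometry: TankGeometry, x0: float, y0: float, sigma: float,
                       amplitude: float = 1.0,
                       diffusivity: float = DEFAULT_DIFFUSIVITY) -> PreyField:
    """Isotropic Gaussian prey blob (test/diagnostic initial condition)."""
    xc, yc = np.meshgrid(geometry.x_centers, geometry.y_centers, indexing="ij")
    F = amplitude * np.exp(-((xc - x0) ** 2 + (yc - y0) ** 2) / (2 * sigma**2))
    return PreyField(geometry, F, diffusivity)


def prey_direction(prey: PreyField, position) -> tuple[float, bool]:
    """Prey direction delta_F at one position.

    Returns ``(angle, ok)`` where the angle is the full-quadrant arctangent
    ``atan2(dF/dy, dF/dx)`` pointing up the prey gradient, and ``ok`` is
    False when the gradient magnitude is below :data:`GRADIENT_EPS`
    (couplings using delta_F must then be suppressed).
    """
    from .simulation import sample_center_field  # local import avoids a cycle

    g = prey.geometry
    x, y = float(position[0]), float(position[1])
    if not bool(g.contains(x, y)):
        raise ValueError(f"position ({x}, {y}) outside the tank")
    gx, gy = prey.gradient()
    fx = float(sample_center_field(gx, g, np.array([x]), np.array([y]))[0])
    fy = float(sample_center_field(gy, g, np.array([x]), np.array([y]))[0])
    mag = float(np.hypot(fx, fy))
    if mag < GRADIENT_EPS:
        return 0.0, False
    return float(np.arctan2(fy, fx)), True
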