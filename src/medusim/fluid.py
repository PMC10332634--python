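"""2D incompressible flow on a staggered (MAC) grid with SOR projection.

The solver advances the Navier-Stokes equations with a second-order
explicit advection-diffusion step (Adams-Bashforth 2 after a forward-Euler
start) followed by a Chorin pressure projection.  The pressure Poisson
equation is solved with red-black Successive Over-Relaxation.

Staggering convention (``g`` is the :class:`~medusim.geometry.TankGeometry`):

* ``u`` on x-normal faces, shape ``(g.nx, g.ny - 1)`` at ``(x_nodes, y_centers)``
* ``v`` on y-normal faces, shape ``(g.nx - 1, g.ny)`` at ``(x_centers, y_nodes)``
* ``p`` at cell centers, shape ``(g.nx - 1, g.ny - 1)``

Tangential wall conditions are imposed through ghost values computed on the
fly (see :func:`padded_u` / :func:`padded_v`); normal boundary faces are set
by :func:`apply_boundary_conditions`.

Analytic steady profiles (Poiseuille channel, single- and double-gyre
stream-function flows) are provided for frozen-flow agent runs; they are
discretely divergence free by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import TankGeometry


@dataclass
class FluidParams:
    """Fluid constants and numerical settings.

    Density 1000 kg m^-3 and an effective dynamic viscosity of
    0.4 N s m^-2 give Re = 4500 for the default channel.  The lid / moving
    side walls translate at 0.4 m s^-1, the channel inflow peaks at
    0.045 m s^-1 (directed toward -x).
    """

    rho: float = 1000.0            # [kg m^-3]
    mu: float = 0.4                # [N s m^-2]
    dt: float = 0.001              # fluid time step [s]
    sor_omega: float = 1.7         # SOR relaxation factor
    sor_tol: float = 1e-4          # relative residual tolerance
    sor_max_iter: int = 10_000
    lid_speed: float = 0.4         # cavity lid / double-gyre wall speed [m s^-1]
    inflow_peak: float = 0.045     # channel peak inflow magnitude [m s^-1]

    @property
    def nu(self) -> float:
        """Kinematic viscosity [m^2 s^-1]."""
        return self.mu / self.rho


class SORConvergenceError(RuntimeError):
    """Raised when the pressure solve stalls; carries the final residual."""

    def __init__(self, iterations: int, residual: float, tol: float):
        self.iterations = iterations
        self.residual = residual
        super().__init__(
            f"SOR pressure solve did not reach tol={tol:g} within "
            f"{iterations} iterations (residual {residual:g})"
        )


class CFLError(RuntimeError):
    pass


@dataclass
class FlowField:
    """Staggered velocity/pressure state of one tank."""

    geometry: TankGeometry
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    time: float = 0.0
    # previous advection-diffusion tendencies for the AB2 scheme
    _ru_prev: np.ndarray | None = field(default=None, repr=False)
    _rv_prev: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def zeros(cls, geometry: TankGeometry) -> "FlowField":
        nx, ny = geometry.nx, geometry.ny
        return cls(
            geometry,
            np.zeros((nx, ny - 1)),
            np.zeros((nx - 1, ny)),
            np.zeros((nx - 1, ny - 1)),
        )

    def copy(self) -> "FlowField":
        return FlowField(
            self.geometry,
            self.u.copy(),
            self.v.copy(),
            self.p.copy(),
            self.time,
            None if self._ru_prev is None else self._ru_prev.copy(),
            None if self._rv_prev is None else self._rv_prev.copy(),
        )

    def divergence(self) -> np.ndarray:
        g = self.geometry
        return (self.u[1:, :] - self.u[:-1, :]) / g.dx + (self.v[:, 1:] - self.v[:, :-1]) / g.dy

    def max_speed(self) -> float:
        return max(float(np.abs(self.u).max()), float(np.abs(self.v).max()))


# ---------------------------------------------------------------------------
# boundary conditions
# ---------------------------------------------------------------------------

def _tangential_speeds(geometry: TankGeometry, params: FluidParams):
    """(u_bottom, u_top, v_left, v_right) tangential wall speeds."""
    s = geometry.scenario
    if s == "cavity":
        return 0.0, params.lid_speed, 0.0, 0.0
    if s == "channel":
        return 0.0, 0.0, None, 0.0  # None: zero-gradient at the outflow (left)
    if s == "double_gyre":
        return 0.0, 0.0, params.lid_speed, params.lid_speed
    raise ValueError(f"unknown scenario {s!r}")


def padded_u(field: FlowField, params: FluidParams) -> np.ndarray:
    """u with one ghost layer in y encoding the tangential wall condition."""
    u_bot, u_top, _, _ = _tangential_speeds(field.geometry, params)
    nxu, ncy = field.u.shape
    up = np.empty((nxu, ncy + 2))
    up[:, 1:-1] = field.u
    up[:, 0] = 2.0 * u_bot - field.u[:, 0]
    up[:, -1] = 2.0 * u_top - field.u[:, -1]
    return up


def padded_v(field: FlowField, params: FluidParams) -> np.ndarray:
    """v with one ghost layer in x encoding the tangential wall condition."""
    _, _, v_left, v_right = _tangential_speeds(field.geometry, params)
    ncx, nyv = field.v.shape
    vp = np.empty((ncx + 2, nyv))
    vp[1:-1, :] = field.v
    if v_left is None:  # channel outflow: zero gradient
        vp[0, :] = field.v[0, :]
    else:
        vp[0, :] = 2.0 * v_left - field.v[0, :]
    vp[-1, :] = 2.0 * v_right - field.v[-1, :]
    return vp


def poiseuille_profile(y: np.ndarray, geometry: TankGeometry, peak: float) -> np.ndarray:
    """Fully developed channel profile, peak speed ``-peak`` toward -x."""
    h = geometry.ly
    q = (np.asarray(y) - geometry.y_min) / h
    return -peak * 4.0 * q * (1.0 - q)


def apply_boundary_conditions(field: FlowField, geometry: TankGeometry | None = None,
                              params: FluidParams | None = None) -> FlowField:
    """Impose the scenario's normal-velocity boundary faces in place.

    cavity / double_gyre: all walls impermeable (moving walls are purely
    tangential).  channel: Poiseuille inflow on the right boundary,
    zero-gradient outflow on the left corrected for global mass balance.
    """
    g = geometry or field.geometry
    params = params or FluidParams()
    s = g.scenario
    field.u[0, :] = 0.0
    field.u[-1, :] = 0.0
    field.v[:, 0] = 0.0
    field.v[:, -1] = 0.0
    if s == "channel":
        inflow = poiseuille_profile(g.y_centers, g, params.inflow_peak)
        field.u[-1, :] = inflow
        # zero-gradient outflow, then a uniform shift enforcing sum(out) = sum(in)
        out = field.u[1, :].copy()
        out += (inflow.sum() - out.sum()) / out.size
        field.u[0, :] = out
    return field


# ---------------------------------------------------------------------------
# advection-diffusion tendencies
# ---------------------------------------------------------------------------

def advection_diffusion_rhs(field: FlowField, params: FluidParams):
    """Tendencies of interior u and v faces: -(a . grad)a + nu laplace(a).

    Second-order central differences; tangential wall values enter through
    ghost layers.  Returns ``(ru, rv)`` with ``ru`` for ``u[1:-1, :]`` and
    ``rv`` for ``v[:, 1:-1]``.
    """
    g = field.geometry
    dx, dy = g.dx, g.dy
    nu = params.nu
    u, v = field.u, field.v
    up = padded_u(field, params)
    vp = padded_v(field, params)

    # --- u faces (interior in x) ---
    uc = u[1:-1, :]
    dudx = (u[2:, :] - u[:-2, :]) / (2 * dx)
    dudy = (up[1:-1, 2:] - up[1:-1, :-2]) / (2 * dy)
    lap_u = (
        (u[2:, :] - 2 * uc + u[:-2, :]) / dx**2
        + (up[1:-1, 2:] - 2 * up[1:-1, 1:-1] + up[1:-1, :-2]) / dy**2
    )
    # v interpolated to interior u points: mean of the 4 surrounding v faces
    v_at_u = 0.25 * (v[:-1, :-1] + v[1:, :-1] + v[:-1, 1:] + v[1:, 1:])
    ru = -(uc * dudx + v_at_u * dudy) + nu * lap_u

    # --- v faces (interior in y) ---
    vc = v[:, 1:-1]
    dvdy = (v[:, 2:] - v[:, :-2]) / (2 * dy)
    dvdx = (vp[2:, 1:-1] - vp[:-2, 1:-1]) / (2 * dx)
    lap_v = (
        (v[:, 2:] - 2 * vc + v[:, :-2]) / dy**2
        + (vp[2:, 1:-1] - 2 * vp[1:-1, 1:-1] + vp[:-2, 1:-1]) / dx**2
    )
    u_at_v = 0.25 * (u[:-1, :-1] + u[:-1, 1:] + u[1:, :-1] + u[1:, 1:])
    rv = -(u_at_v * dvdx + vc * dvdy) + nu * lap_v
    return ru, rv


# ---------------------------------------------------------------------------
# pressure projection
# ---------------------------------------------------------------------------

def sor_pressure_solve(rhs: np.ndarray, dx: float, p0: np.ndarray,
                       params: FluidParams) -> np.ndarray:
    """Solve laplace(p) = rhs with homogeneous Neumann walls by red-black SOR.

    The Neumann problem is singular; the mean of p is removed every sweep.
    Raises :class:`SORConvergenceError` on stall.
    """
    ncx, ncy = rhs.shape
    P = np.zeros((ncx + 2, ncy + 2))
    P[1:-1, 1:-1] = p0
    ii, jj = np.meshgrid(np.arange(ncx), np.arange(ncy), indexing="ij")
    red = ((ii + jj) % 2 == 0)
    black = ~red
    omega = params.sor_omega
    h2 = dx * dx
    rhs_norm = float(np.sqrt((rhs**2).sum()))
    scale = max(rhs_norm, 1e-300)

    def _ghosts():
        P[0, :] = P[1, :]
        P[-1, :] = P[-2, :]
        P[:, 0] = P[:, 1]
        P[:, -1] = P[:, -2]

    for it in range(params.sor_max_iter):
        for mask in (red, black):
            _ghosts()
            inner = P[1:-1, 1:-1]
            gs = 0.25 * (P[2:, 1:-1] + P[:-2, 1:-1] + P[1:-1, 2:] + P[1:-1, :-2] - h2 * rhs)
            inner[mask] += omega * (gs[mask] - inner[mask])
        P[1:-1, 1:-1] -= P[1:-1, 1:-1].mean()
        _ghosts()
        res = (
            P[2:, 1:-1] + P[:-2, 1:-1] + P[1:-1, 2:] + P[1:-1, :-2]
            - 4 * P[1:-1, 1:-1]
        ) / h2 - rhs
        res_norm = float(np.sqrt((res**2).sum()))
        if rhs_norm == 0.0 and res_norm < 1e-14:
            break
        if res_norm / scale < params.sor_tol:
            break
    else:
        raise SORConvergenceError(params.sor_max_iter, res_norm / scale, params.sor_tol)
    return P[1:-1, 1:-1].copy()


def project(field: FlowField, params: FluidParams) -> FlowField:
    """Make the velocity field divergence free (in place)."""
    g = field.geometry
    div = field.divergence()
    rhs = div * (params.rho / params.dt)
    p = sor_pressure_solve(rhs, g.dx, field.p, params)
    field.p = p
    c = params.dt / params.rho
    field.u[1:-1, :] -= c * (p[1:, :] - p[:-1, :]) / g.dx
    field.v[:, 1:-1] -= c * (p[:, 1:] - p[:, :-1]) / g.dy
    return field


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------

def step_flow(field: FlowField, params: FluidParams,
              geometry: TankGeometry | None = None) -> FlowField:
    """Advance one fluid time step (in place); returns the field.

    Adams-Bashforth-2 advection-diffusion predictor (forward Euler on the
    first step), then SOR pressure projection.  Raises :class:`CFLError`
    when ``max|velocity| * dt / dx > 1``.
    """
    g = geometry or field.geometry
    dt = params.dt
    cfl = field.max_speed() * dt / min(g.dx, g.dy)
    if cfl > 1.0:
        raise CFLError(f"advective CFL {cfl:.3f} > 1 at t={field.time:.3f}s")

    ru, rv = advection_diffusion_rhs(field, params)
    if field._ru_prev is None:
        du, dv = ru, rv
    else:
        du = 1.5 * ru - 0.5 * field._ru_prev
        dv = 1.5 * rv - 0.5 * field._rv_prev
    field.u[1:-1, :] += dt * du
    field.v[:, 1:-1] += dt * dv
    field._ru_prev, field._rv_prev = ru, rv

    apply_boundary_conditions(field, g, params)
    project(field, params)
    field.time += dt
    return field


def reynolds_number(params: FluidParams, u_scale: float, l_scale: float) -> float:
    """Re = rho * U * L / mu for positive scales (U may be zero)."""
    if u_scale < 0 or l_scale <= 0:
        raise ValueError("scales must be positive (U may be zero)")
    return params.rho * u_scale * l_scale / params.mu


# ---------------------------------------------------------------------------
# vorticity
# ---------------------------------------------------------------------------

def vorticity(field: FlowField) -> np.ndarray:
    """Curl C = dv/dx - du/dy at grid nodes, shape ``(nx, ny)``.

    Central differences at interior nodes, one-sided at the boundary.
    """
    g = field.geometry
    u, v = field.u, field.v
    nx, ny = g.nx, g.ny
    dvdx = np.empty((nx, ny))
    dvdx[1:-1, :] = (v[1:, :] - v[:-1, :]) / g.dx
    dvdx[0, :] = dvdx[1, :]
    dvdx[-1, :] = dvdx[-2, :]
    dudy = np.empty((nx, ny))
    dudy[:, 1:-1] = (u[:, 1:] - u[:, :-1]) / g.dy
    dudy[:, 0] = dudy[:, 1]
    dudy[:, -1] = dudy[:, -2]
    return dvdx - dudy


def _node_gradient(fld: np.ndarray, dx: float, dy: float):
    gx = np.empty_like(fld)
    gx[1:-1, :] = (fld[2:, :] - fld[:-2, :]) / (2 * dx)
    gx[0, :] = (fld[1, :] - fld[0, :]) / dx
    gx[-1, :] = (fld[-1, :] - fld[-2, :]) / dx
    gy = np.empty_like(fld)
    gy[:, 1:-1] = (fld[:, 2:] - fld[:, :-2]) / (2 * dy)
    gy[:, 0] = (fld[:, 1] - fld[:, 0]) / dy
    gy[:, -1] = (fld[:, -1] - fld[:, -2]) / dy
    return gx, gy


def vorticity_fields(field: FlowField):
    """Absolute vorticity |C| and its gradient on grid nodes.

    Returns ``(absC, dCdx, dCdy)``; |C| is the local turbulence proxy the
    agents respond to.
    """
    g = field.geometry
    abs_c = np.abs(vorticity(field))
    gx, gy = _node_gradient(abs_c, g.dx, g.dy)
    return abs_c, gx, gy


# ---------------------------------------------------------------------------
# analytic (frozen) flows
# ---------------------------------------------------------------------------

def _streamfunction_flow(geometry: TankGeometry, psi_nodes: np.ndarray) -> FlowField:
    """Staggered velocities from a node stream function (u = dpsi/dy, v = -dpsi/dx).

    Discretely divergence free by construction.
    """
    g = geometry
    u = (psi_nodes[:, 1:] - psi_nodes[:, :-1]) / g.dy
    v = -(psi_nodes[1:, :] - psi_nodes[:-1, :]) / g.dx
    return FlowField(g, u, v, np.zeros((g.nx - 1, g.ny - 1)))


def analytic_flow(geometry: TankGeometry, params: FluidParams | None = None,
                  peak_speed: float = 0.1) -> FlowField:
    """Steady analytic flow for frozen-flow agent runs.

    channel: exact Poiseuille everywhere.  cavity: single clockwise gyre;
    double_gyre: two counter-rotating gyres (side walls moving up), both
    from sinusoidal stream functions with interior peak speed
    ``peak_speed`` (default 0.1 m s^-1, a typical interior magnitude for a
    0.4 m s^-1 driven wall).
    """
    g = geometry
    params = params or FluidParams()
    if g.scenario == "channel":
        fieldv = FlowField.zeros(g)
        fieldv.u[:, :] = poiseuille_profile(g.y_centers, g, params.inflow_peak)[None, :]
        return fieldv
    xn, yn = np.meshgrid(g.x_nodes - g.x_min, g.y_nodes - g.y_min, indexing="ij")
    if g.scenario == "cavity":
        kx = np.pi / g.lx
        psi0 = -peak_speed * g.ly / np.pi  # clockwise primary gyre (C < 0)
        psi = psi0 * np.sin(kx * xn) * np.sin(np.pi * yn / g.ly)
    elif g.scenario == "double_gyre":
        kx = 2 * np.pi / g.lx
        psi0 = -peak_speed * g.ly / np.pi  # walls moving +y at both sides
        psi = psi0 * np.sin(kx * xn) * np.sin(np.pi * yn / g.ly)
    else:
        raise ValueError(f"no analytic profile for scenario {g.scenario!r}")
    return _streamfunction_flow(g, psi)
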