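"""Time-stepping engine: stochastic Heun integration of agent ensembles.

Agents are advanced with a predictor-corrector (Heun) scheme in which the
Wiener increment of the colored angular noise is shared between the two
stages.  Field quantities (flow velocity, absolute vorticity and its
gradient, prey concentration and gradient) are sampled at agent positions
by bilinear interpolation from their native staggered/node/center grids.

Flow modes
----------
``analytic``  frozen closed-form profile for the scenario (default; the
              coupling is one-way, so agent ensembles can replay a steady
              flow without re-running the CFD),
``frozen``    a user-supplied :class:`~medusim.fluid.FlowField` snapshot,
``live``      the CFD solver advanced alongside the agents.

A passive or repulsive tracer twin with identical initial positions can be
integrated alongside the active ensemble; all Delta statistics compare the
two.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from types import SimpleNamespace

import numpy as np
import pandas as pd

from . import agents as ag
from .agents import ModelParams, wrap_angle
from .fluid import FlowField, FluidParams, analytic_flow, step_flow, vorticity_fields
from .geometry import TankGeometry
from .prey import PreyField, init_double_gyre_prey, step_prey

logger = logging.getLogger(__name__)

#: safety clamp distance from the walls after each step [m]
WALL_CLAMP = 1e-6


# ---------------------------------------------------------------------------
# field sampling
# ---------------------------------------------------------------------------

def _bilinear(arr: np.ndarray, x0: float, y0: float, dx: float, dy: float,
              xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Bilinear interpolation on a regular grid, constant beyond its hull."""
    nx, ny = arr.shape
    gx = np.clip((np.asarray(xs) - x0) / dx, 0.0, nx - 1 - 1e-12)
    gy = np.clip((np.asarray(ys) - y0) / dy, 0.0, ny - 1 - 1e-12)
    i = gx.astype(int)
    j = gy.astype(int)
    fx = gx - i
    fy = gy - j
    return (
        arr[i, j] * (1 - fx) * (1 - fy)
        + arr[i + 1, j] * fx * (1 - fy)
        + arr[i, j + 1] * (1 - fx) * fy
        + arr[i + 1, j + 1] * fx * fy
    )


def sample_node_field(arr: np.ndarray, g: TankGeometry, x, y) -> np.ndarray:
    return _bilinear(arr, g.x_min, g.y_min, g.dx, g.dy, x, y)


def sample_center_field(arr: np.ndarray, g: TankGeometry, x, y) -> np.ndarray:
    return _bilinear(arr, g.x_min + g.dx / 2, g.y_min + g.dy / 2, g.dx, g.dy, x, y)


def sample_u(flow: FlowField, x, y) -> np.ndarray:
    g = flow.geometry
    return _bilinear(flow.u, g.x_min, g.y_min + g.dy / 2, g.dx, g.dy, x, y)


def sample_v(flow: FlowField, x, y) -> np.ndarray:
    g = flow.geometry
    return _bilinear(flow.v, g.x_min + g.dx / 2, g.y_min, g.dx, g.dy, x, y)


def sample_field(arr: np.ndarray, kind: str, g: TankGeometry, x, y) -> np.ndarray:
    """Sample a grid field of a given staggering at positions inside the tank.

    ``kind`` is one of ``node``, ``center``, ``face_u``, ``face_v``.
    Positions outside the tank raise ValueError.  Staggered components are
    interpolated from their own face grids (constant continuation over the
    half-cell strip next to the wall).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if not np.all(g.contains(x, y)):
        raise ValueError("sample position outside the tank")
    if kind == "node":
        return sample_node_field(arr, g, x, y)
    if kind == "center":
        return sample_center_field(arr, g, x, y)
    if kind == "face_u":
        return _bilinear(arr, g.x_min, g.y_min + g.dy / 2, g.dx, g.dy, x, y)
    if kind == "face_v":
        return _bilinear(arr, g.x_min + g.dx / 2, g.y_min, g.dx, g.dy, x, y)
    raise ValueError(f"unknown field kind {kind!r}")


class EnvironmentSampler:
    """Caches flow- and prey-derived grids and samples them at agent positions."""

    def __init__(self, flow: FlowField, prey: PreyField | None = None):
        self.flow = flow
        self.prey = prey
        self.refresh_flow()
        self.refresh_prey()

    def refresh_flow(self) -> None:
        self._abs_c, self._gcx, self._gcy = vorticity_fields(self.flow)

    def refresh_prey(self) -> None:
        if self.prey is None:
            self._gfx = self._gfy = None
        else:
            self._gfx, self._gfy = self.prey.gradient()

    def sample(self, x: np.ndarray, y: np.ndarray) -> SimpleNamespace:
        g = self.flow.geometry
        ux = sample_u(self.flow, x, y)
        uy = sample_v(self.flow, x, y)
        absc = sample_node_field(self._abs_c, g, x, y)
        gcx = sample_node_field(self._gcx, g, x, y)
        gcy = sample_node_field(self._gcy, g, x, y)
        if self.prey is None:
            f = np.zeros_like(ux)
            gfx = np.zeros_like(ux)
            gfy = np.zeros_like(ux)
        else:
            f = sample_center_field(self.prey.F, g, x, y)
            gfx = sample_center_field(self._gfx, g, x, y)
            gfy = sample_center_field(self._gfy, g, x, y)
        return SimpleNamespace(Ux=ux, Uy=uy, absC=absc, gCx=gcx, gCy=gcy,
                               F=f, gFx=gfx, gFy=gfy)


def directions(env: SimpleNamespace):
    """Direction angles (delta_U, delta_C, delta_F) and validity masks.

    Full-quadrant arctangents of (y-component, x-component); a direction is
    degenerate when its defining vector is shorter than 1e-8 in native units
    and the corresponding coupling must be dropped.
    """
    eps = ag.DIRECTION_EPS
    d_u = np.arctan2(env.Uy, env.Ux)
    ok_u = np.hypot(env.Ux, env.Uy) >= eps
    d_c = np.arctan2(env.gCy, env.gCx)
    ok_c = np.hypot(env.gCx, env.gCy) >= eps
    d_f = np.arctan2(env.gFy, env.gFx)
    ok_f = np.hypot(env.gFx, env.gFy) >= eps
    return (d_u, d_c, d_f), (ok_u, ok_c, ok_f)


# ---------------------------------------------------------------------------
# ensemble state and stepping
# ---------------------------------------------------------------------------

@dataclass
class AgentEnsembleState:
    """Per-agent state arrays (x, y, theta, phi, A, L)."""

    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    A: np.ndarray
    L: np.ndarray

    def copy(self) -> "AgentEnsembleState":
        return AgentEnsembleState(*(getattr(self, k).copy()
                                    for k in ("x", "y", "theta", "phi", "A", "L")))

    @property
    def n(self) -> int:
        return self.x.size


def _rhs(state_vals, env, geometry: TankGeometry, params: ModelParams,
         rng: np.random.Generator):
    """Deterministic tendencies of (x, y, theta, phi, A) and the L drift."""
    x, y, theta, phi, A, L = state_vals
    (d_u, d_c, d_f), ok = directions(env)
    eps = ag.coupling_strengths(A, env.F, params)
    dtheta = ag.orientation_rhs(theta, L, eps, (d_u, d_c, d_f), ok, params)
    dphi = ag.bell_frequency(A, params)  # phase coupling H(.) disabled
    grad_f_mag = np.hypot(env.gFx, env.gFy)
    dA = ag.activity_rhs(theta, A, grad_f_mag, d_f, ok[2], params)
    vx, vy = ag.positional_rhs(x, y, theta, phi, A, env, geometry, params, rng)
    dL = -params.lambda_theta * L
    return vx, vy, dtheta, dphi, dA, dL


def _clamp(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.clip(x, lo + WALL_CLAMP, hi - WALL_CLAMP)


def heun_step(state: AgentEnsembleState, sampler: EnvironmentSampler,
              geometry: TankGeometry, params: ModelParams, dt: float,
              rng: np.random.Generator) -> AgentEnsembleState:
    """Advance the ensemble one stochastic Heun step (in place).

    One Wiener increment per agent is drawn and reused in the predictor and
    corrector; the noise intensity D(A) is taken at the step's start state.
    Angles are wrapped and positions clamped to the tank interior after the
    update.  Non-finite states raise with the offending agent index.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x, y, th, ph, A, L = state.x, state.y, state.theta, state.phi, state.A, state.L
    for name, arr in (("x", x), ("y", y), ("theta", th), ("phi", ph), ("A", A), ("L", L)):
        if not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise FloatingPointError(f"non-finite {name} for agent {bad}")
    xi = rng.standard_normal(x.size)
    s = np.sqrt(2.0 * ag.noise_intensity(A, params) * dt)

    env1 = sampler.sample(x, y)
    k1 = _rhs((x, y, th, ph, A, L), env1, geometry, params, rng)

    xp = _clamp(x + dt * k1[0], geometry.x_min, geometry.x_max)
    yp = _clamp(y + dt * k1[1], geometry.y_min, geometry.y_max)
    thp = wrap_angle(th + dt * k1[2])
    php = ph + dt * k1[3]
    Ap = A + dt * k1[4]
    Lp = L + dt * k1[5] + s * xi

    env2 = sampler.sample(xp, yp)
    k2 = _rhs((xp, yp, thp, php, Ap, Lp), env2, geometry, params, rng)

    state.x = _clamp(x + 0.5 * dt * (k1[0] + k2[0]), geometry.x_min, geometry.x_max)
    state.y = _clamp(y + 0.5 * dt * (k1[1] + k2[1]), geometry.y_min, geometry.y_max)
    state.theta = wrap_angle(th + 0.5 * dt * (k1[2] + k2[2]))
    state.phi = np.mod(ph + 0.5 * dt * (k1[3] + k2[3]), 2 * np.pi)
    state.A = A + 0.5 * dt * (k1[4] + k2[4])
    state.L = L + 0.5 * dt * (k1[5] + k2[5]) + s * xi

    for name in ("x", "y", "theta", "phi", "A", "L"):
        arr = getattr(state, name)
        if not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise FloatingPointError(f"non-finite {name} for agent {bad}")
    return state


# ---------------------------------------------------------------------------
# run configuration, records, driver
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One simulation run (ensemble of N agents, optionally K repetitions)."""

    scenario: str = "cavity"
    model: ModelParams = field(default_factory=ModelParams)
    fluid: FluidParams = field(default_factory=FluidParams)
    n_agents: int = 128
    n_runs: int = 16
    dt_agent: float = 0.001
    record_interval: float = 0.1
    total_time: float = 300.0
    seed: int = 0
    flow_mode: str = "analytic"          # analytic | frozen | live
    analytic_peak_speed: float = 0.1     # interior peak of the analytic gyres [m s^-1]
    prey_enabled: bool = False
    twin_mode: str | None = None         # None | "passive" | "repulsive"
    init_region: tuple | None = None     # (x_lo, x_hi, y_lo, y_hi)
    init_margin: float = 0.15            # wall margin for initial positions [m]
    geometry: TankGeometry | None = None
    flow_snapshot: FlowField | None = None

    def resolved_geometry(self) -> TankGeometry:
        return self.geometry or TankGeometry.for_scenario(self.scenario)


@dataclass
class TrajectoryRecord:
    """Time-indexed per-agent trajectories and locally sampled fields."""

    times: np.ndarray
    data: dict  # name -> (n_times, n_agents) arrays

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name]

    @property
    def n_agents(self) -> int:
        return next(iter(self.data.values())).shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        t_grid, idx = np.meshgrid(self.times, np.arange(self.n_agents), indexing="ij")
        cols = {"time": t_grid.ravel(), "agent": idx.ravel()}
        cols.update({k: v.ravel() for k, v in self.data.items()})
        return pd.DataFrame(cols)


@dataclass
class SimulationResult:
    config: RunConfig
    record: TrajectoryRecord
    twin: TrajectoryRecord | None = None
    flow: FlowField | None = None
    prey: PreyField | None = None


def default_init_region(config: RunConfig, geometry: TankGeometry) -> tuple:
    """Scenario-specific initial-position region.

    Cavity: whole tank.  Double gyre: right gyre (x > 0), away from the prey.
    Channel: the downstream quarter — the swarm swims upstream for the whole
    run, so releasing it near the outflow keeps it clear of the inlet wall.
    """
    m = config.init_margin
    g = geometry
    if config.init_region is not None:
        return config.init_region
    if g.scenario == "channel":
        return (g.x_min + 0.5, g.x_min + 0.25 * g.lx, g.y_min + m, g.y_max - m)
    if g.scenario == "double_gyre":
        return (0.5 * (g.x_min + g.x_max) + m, g.x_max - m, g.y_min + m, g.y_max - m)
    return (g.x_min + m, g.x_max - m, g.y_min + m, g.y_max - m)


def initial_state(config: RunConfig, geometry: TankGeometry,
                  rng: np.random.Generator) -> AgentEnsembleState:
    """Uniform positions in the scenario region; theta, phi uniform on the
    circle; A = 0; L from its stationary normal distribution."""
    n = config.n_agents
    x_lo, x_hi, y_lo, y_hi = default_init_region(config, geometry)
    x = rng.uniform(x_lo, x_hi, n)
    y = rng.uniform(y_lo, y_hi, n)
    theta = rng.uniform(-np.pi, np.pi, n)
    phi = rng.uniform(0.0, 2 * np.pi, n)
    A = np.zeros(n)
    L = rng.normal(0.0, ag.ou_stationary_std(config.model.D0, config.model.lambda_theta), n)
    return AgentEnsembleState(x, y, theta, phi, A, L)


def tracer_params(params: ModelParams, mode: str) -> ModelParams:
    """Reduced tracer dynamics: passive (advection + walls) or repulsive."""
    if mode not in ("passive", "repulsive"):
        raise ValueError(f"unknown twin mode {mode!r}")
    return replace(params, active=False, repulsion=(mode == "repulsive"),
                   attraction=False, activity_dynamics=False)


def build_flow(config: RunConfig, geometry: TankGeometry) -> FlowField:
    if config.flow_mode == "analytic":
        return analytic_flow(geometry, config.fluid, config.analytic_peak_speed)
    if config.flow_mode == "frozen":
        if config.flow_snapshot is None:
            raise ValueError("frozen flow mode requires a flow_snapshot")
        return config.flow_snapshot.copy()
    if config.flow_mode == "live":
        if config.flow_snapshot is not None:
            fieldv = config.flow_snapshot.copy()
        else:
            fieldv = FlowField.zeros(geometry)
        from .fluid import apply_boundary_conditions
        apply_boundary_conditions(fieldv, geometry, config.fluid)
        return fieldv
    raise ValueError(f"unknown flow mode {config.flow_mode!r}")


def run(config: RunConfig, seed_seq: np.random.SeedSequence | None = None) -> SimulationResult:
    """Integrate one run; optionally a tracer twin with identical initial
    positions (its own independent noise stream, though tracers consume none).
    """
    geometry = config.resolved_geometry()
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(config.seed)
    ss_main, ss_twin = seed_seq.spawn(2)
    rng = np.random.default_rng(ss_main)
    rng_twin = np.random.default_rng(ss_twin)

    flow = build_flow(config, geometry)
    prey = init_double_gyre_prey(geometry) if config.prey_enabled else None
    sampler = EnvironmentSampler(flow, prey)

    state = initial_state(config, geometry, rng)
    twin_state = state.copy() if config.twin_mode else None
    twin_params = tracer_params(config.model, config.twin_mode) if config.twin_mode else None

    dt = config.dt_agent
    n_steps = int(round(config.total_time / dt))
    rec_every = max(1, int(round(config.record_interval / dt)))

    live = config.flow_mode == "live"
    if live:
        n_sub = int(round(dt / config.fluid.dt))
        if n_sub < 1 or abs(n_sub * config.fluid.dt - dt) > 1e-12:
            raise ValueError("dt_agent must be a positive multiple of the fluid dt in live mode")
    prey_sub = 1
    if prey is not None:
        prey_sub = max(1, math.ceil(dt / prey.stable_dt(flow)))

    rec: dict[str, list] = {k: [] for k in
                            ("x", "y", "theta", "phi", "A", "vx", "vy", "Ux", "Uy", "absC", "F")}
    rec_twin: dict[str, list] = {k: [] for k in ("x", "y", "vx", "vy", "Ux", "Uy", "absC", "F")}
    times = []

    def _record():
        times.append(step * dt)
        env = sampler.sample(state.x, state.y)
        k = _rhs((state.x, state.y, state.theta, state.phi, state.A, state.L),
                 env, geometry, config.model, rng)
        for name, val in (("x", state.x), ("y", state.y), ("theta", state.theta),
                          ("phi", state.phi), ("A", state.A), ("vx", k[0]), ("vy", k[1]),
                          ("Ux", env.Ux), ("Uy", env.Uy), ("absC", env.absC), ("F", env.F)):
            rec[name].append(val.copy())
        if twin_state is not None:
            env_t = sampler.sample(twin_state.x, twin_state.y)
            kt = _rhs((twin_state.x, twin_state.y, twin_state.theta, twin_state.phi,
                       twin_state.A, twin_state.L), env_t, geometry, twin_params, rng_twin)
            for name, val in (("x", twin_state.x), ("y", twin_state.y), ("vx", kt[0]),
                              ("vy", kt[1]), ("Ux", env_t.Ux), ("Uy", env_t.Uy),
                              ("absC", env_t.absC), ("F", env_t.F)):
                rec_twin[name].append(val.copy())

    logger.info("run start: scenario=%s N=%d T=%.1fs dt=%.4gs flow=%s twin=%s",
                geometry.scenario, config.n_agents, config.total_time, dt,
                config.flow_mode, config.twin_mode)
    step = 0
    _record()
    for step in range(1, n_steps + 1):
        if live:
            for _ in range(n_sub):
                step_flow(flow, config.fluid, geometry)
            sampler.refresh_flow()
        if prey is not None:
            for _ in range(prey_sub):
                step_prey(prey, flow, dt / prey_sub)
            sampler.refresh_prey()
        heun_step(state, sampler, geometry, config.model, dt, rng)
        if twin_state is not None:
            heun_step(twin_state, sampler, geometry, twin_params, dt, rng_twin)
        if step % rec_every == 0:
            _record()

    logger.info("run done: %d steps, %d records", n_steps, len(times))
    record = TrajectoryRecord(np.asarray(times), {k: np.asarray(v) for k, v in rec.items()})
    twin_rec = None
    if twin_state is not None:
        twin_rec = TrajectoryRecord(np.asarray(times),
                                    {k: np.asarray(v) for k, v in rec_twin.items()})
    return SimulationResult(config, record, twin_rec, flow, prey)


def run_ensemble(config: RunConfig) -> list[SimulationResult]:
    """K independent repetitions with per-run streams spawned from the master seed."""
    root = np.random.SeedSequence(config.seed)
    return [run(config, seed_seq=ss) for ss in root.spawn(config.n_runs)]
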