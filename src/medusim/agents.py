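"""Right-hand sides of the four-variable jellyfish agent dynamics.

Each agent carries position ``(x, y)`` [m], a body orientation ``theta``
[rad, wrapped to (-pi, pi]], a bell-pulsation phase ``phi`` [rad, mod 2pi],
a non-negative activity ``A`` (dimensionless excitation driven by the prey
gradient, decaying at rate ``lambda_A``) and a colored angular drift ``L``
[rad s^-1] following an Ornstein-Uhlenbeck process.

All behavioural switches go through one saturating response function

    R(a, b, S) = a S / (b + S)

quasi-linear with slope a/b for small stimulus S, saturating to a.  The
activity gates the bell frequency, the angular noise intensity, the speed
and the three angular couplings (counter-current, turbulence avoidance,
prey attraction); ambient prey concentration decouples the counter-current
term.  Functions are vectorised over the agent axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import i0

from .geometry import TankGeometry

#: magnitude below which a direction angle is degenerate and its coupling dropped
DIRECTION_EPS = 1e-8

#: pair distance below which the soft-core repulsion is capped
COINCIDENT_EPS = 1e-9


@dataclass
class ModelParams:
    """All agent-model parameters (printed defaults) plus mechanism toggles.

    Units in names where ambiguous; angles rad, lengths m, times s.
    """

    # interaction
    R_i: float = 0.1               # agent-agent interaction radius [m]
    R_w: float = 0.1               # wall repulsion radius [m]
    # angular (colored) noise
    lambda_theta: float = 5.0      # OU relaxation rate [s^-1]
    D0: float = 0.1                # noise intensity, inactive state [rad^2 s^-3]
    # propulsion
    V0: float = 0.15               # max propulsion speed, inactive [m s^-1]
    Va: float = 0.5                # speed response amplitude [m s^-1]
    Vb: float = 0.6                # speed response half-saturation [m s^-1]
    J: float = 1.0                 # bell-pulsation shape parameter [-]
    # angular couplings (inactive-state values)
    eps_U0: float = 0.16           # counter-current [rad s^-1]
    eps_C0: float = 0.08           # turbulence avoidance [rad s^-1]
    eps_F0: float = 0.16           # prey orientation [rad s^-1]
    # bell oscillator
    omega0: float = 1.2            # natural bell frequency [rad s^-1]
    # activity
    lambda_A: float = 0.005        # activity decay rate [s^-1]
    # response parameters
    f_phi: float = 0.75            # frequency response [-]
    f_theta: float = 0.75          # noise response [-]
    f_U: float = 0.05              # counter-current decoupling [F_0]
    f_C: float = 0.2               # turbulence decoupling [-]
    f_F: float = 0.2               # prey-coupling activation [-]
    f_g: float = 100.0             # "greediness" (prey-coupling shutoff) [-]

    # --- mechanism toggles -------------------------------------------
    active: bool = True            # self-propulsion (False: advected tracer)
    repulsion: bool = True         # soft-core agent-agent repulsion
    attraction: bool = False       # attractive branch (defined but off)
    phase_coupling: bool = False   # bell phase coupling H(.) (disabled stub)
    counter_current: bool = True   # eps_U sin(theta - delta_U) term
    turbulence_avoidance: bool = True   # eps_C sin(theta - delta_C) term
    prey_orientation: bool = True  # -eps_F sin(theta - delta_F) term
    activity_dynamics: bool = True      # integrate A (else frozen at 0)
    freq_response: bool = True     # omega(A)
    noise_response: bool = True    # D(A)
    flow_decoupling: bool = True   # eps_U(F) parametric switch
    vorticity_decoupling: bool = True   # eps_C(A) parametric switch
    speed_activity_response: bool = True  # V(|U| + A) (else V(|U|))

    def __post_init__(self) -> None:
        for name in ("R_i", "R_w", "lambda_theta", "Vb", "omega0", "lambda_A",
                     "f_phi", "f_theta", "f_U", "f_C", "f_F", "f_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("D0", "V0", "Va", "J", "eps_U0", "eps_C0", "eps_F0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def with_toggles(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


def wrap_angle(theta: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(theta), 2 * np.pi)


# ---------------------------------------------------------------------------
# response function and parametric switches
# ---------------------------------------------------------------------------

def response(a, b, S):
    """Saturating response R(a, b, S) = a S / (b + S); b > 0, S >= 0."""
    if np.any(np.asarray(b) <= 0):
        raise ValueError("response half-saturation b must be positive")
    S = np.asarray(S)
    return a * S / (b + S)


def bell_frequency(A, params: ModelParams):
    """Bell frequency omega(A) = omega0 [1 + R(f_phi, f_phi, A)]."""
    if not params.freq_response:
        return params.omega0 * np.ones_like(np.asarray(A, dtype=float))
    return params.omega0 * (1.0 + response(params.f_phi, params.f_phi, A))


def noise_intensity(A, params: ModelParams):
    """Angular noise intensity D(A) = D0 [1 + R(f_theta, f_theta, A)]."""
    if not params.noise_response:
        return params.D0 * np.ones_like(np.asarray(A, dtype=float))
    return params.D0 * (1.0 + response(params.f_theta, params.f_theta, A))


def coupling_strengths(A, F, params: ModelParams):
    """Instantaneous (eps_U, eps_C, eps_F) after the parametric switches.

    eps_U(F)   = eps_U0 [1 - R(1, f_U, F)]         (prey decouples rheotaxis)
    eps_C(A)   = eps_C0 [1 - R(1, f_C, A)]         (activity decouples avoidance)
    eps_F(A)   = eps_F0 R(1, f_F, A) [1 - R(1, f_g, A)]   (rise then shutoff)
    """
    A = np.asarray(A, dtype=float)
    F = np.asarray(F, dtype=float)
    if params.counter_current:
        eps_u = params.eps_U0 * (1.0 - response(1.0, params.f_U, F)) \
            if params.flow_decoupling else params.eps_U0 * np.ones_like(F)
    else:
        eps_u = np.zeros_like(F)
    if params.turbulence_avoidance:
        eps_c = params.eps_C0 * (1.0 - response(1.0, params.f_C, A)) \
            if params.vorticity_decoupling else params.eps_C0 * np.ones_like(A)
    else:
        eps_c = np.zeros_like(A)
    if params.prey_orientation:
        eps_f = params.eps_F0 * response(1.0, params.f_F, A) * (1.0 - response(1.0, params.f_g, A))
    else:
        eps_f = np.zeros_like(A)
    return eps_u, eps_c, eps_f


# ---------------------------------------------------------------------------
# activity, orientation, bell
# ---------------------------------------------------------------------------

def activity_rhs(theta, A, grad_F_mag, delta_F, delta_F_ok, params: ModelParams):
    """dA/dt = -lambda_A A + |grad F| (|cos d| + cos d)/2, d = theta - delta_F.

    The half-wave rectifier means only swimming within 90 degrees of the
    ascending prey gradient excites the agent.  Degenerate gradients
    (``delta_F_ok`` False) contribute nothing.
    """
    decay = -params.lambda_A * np.asarray(A, dtype=float)
    if not params.activity_dynamics:
        return np.zeros_like(decay)
    d = np.asarray(theta) - np.asarray(delta_F)
    cd = np.cos(d)
    drive = np.asarray(grad_F_mag) * 0.5 * (np.abs(cd) + cd)
    drive = np.where(np.asarray(delta_F_ok, dtype=bool), drive, 0.0)
    return decay + drive


def orientation_rhs(theta, L, eps, deltas, ok, params: ModelParams):
    """dtheta/dt = L + eps_U sin(t-dU) + eps_C sin(t-dC) - eps_F sin(t-dF).

    ``eps = (eps_U, eps_C, eps_F)``, ``deltas = (dU, dC, dF)``,
    ``ok`` are boolean masks flagging well-defined direction angles.
    The +sin terms stabilise the anti-parallel orientation (swim against
    the flow / away from rising |C|); the -sin term stabilises swimming up
    the prey gradient.
    """
    theta = np.asarray(theta, dtype=float)
    eps_u, eps_c, eps_f = eps
    d_u, d_c, d_f = deltas
    ok_u, ok_c, ok_f = (np.asarray(m, dtype=bool) for m in ok)
    out = np.asarray(L, dtype=float) \
        + np.where(ok_u, eps_u * np.sin(theta - d_u), 0.0) \
        + np.where(ok_c, eps_c * np.sin(theta - d_c), 0.0) \
        - np.where(ok_f, eps_f * np.sin(theta - d_f), 0.0)
    return out


def bell_beta(phi, J: float):
    """Bell pulsation factor beta(phi) = exp[J (cos phi - 1)] in (0, 1]."""
    if J < 0:
        raise ValueError("J must be non-negative")
    return np.exp(J * (np.cos(np.asarray(phi)) - 1.0))


def mean_bell_factor(J: float) -> float:
    """Period average of beta: exp(-J) I0(J) (I0 = modified Bessel)."""
    return float(np.exp(-J) * i0(J))


def swim_speed(phi, U_mag, A, params: ModelParams):
    """Instantaneous propulsion speed (V0 + R(Va, Vb, |U|+A)) beta(phi).

    The activity is added raw to the flow speed (the model treats A as
    commensurate with a speed stimulus).
    """
    stim = np.asarray(U_mag, dtype=float)
    if params.speed_activity_response:
        stim = stim + np.asarray(A, dtype=float)
    return (params.V0 + response(params.Va, params.Vb, stim)) * bell_beta(phi, params.J)


def active_velocity(theta, phi, U_mag, A, params: ModelParams):
    """Propulsion velocity vector V * (cos theta, sin theta); zero if inactive."""
    theta = np.asarray(theta, dtype=float)
    if not params.active:
        z = np.zeros_like(theta)
        return z, z.copy()
    V = swim_speed(phi, U_mag, A, params)
    return V * np.cos(theta), V * np.sin(theta)


def angular_noise_step(L, A, dt: float, rng: np.random.Generator, params: ModelParams):
    """One Heun step of the colored angular drift (OU process).

        dL = -lambda_theta L dt + sqrt(2 D(A)) dW

    The Wiener increment is shared between predictor and corrector and the
    state-dependent intensity D(A) is evaluated at the step's start (Ito
    convention).  The stationary standard deviation is sqrt(D/lambda_theta).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    L = np.asarray(L, dtype=float)
    lam = params.lambda_theta
    s = np.sqrt(2.0 * noise_intensity(A, params) * dt)
    xi = rng.standard_normal(L.shape)
    l_pred = L - lam * L * dt + s * xi
    return L + 0.5 * dt * (-lam * L - lam * l_pred) + s * xi


def ou_stationary_std(D: float, lambda_theta: float) -> float:
    """Stationary std of the angular drift, sqrt(D / lambda_theta) [rad s^-1]."""
    return float(np.sqrt(D / lambda_theta))


# ---------------------------------------------------------------------------
# interactions
# ---------------------------------------------------------------------------

def pairwise_interaction(x, y, params: ModelParams, rng: np.random.Generator | None = None):
    """Soft-core neighbour velocities: mean over neighbours within R_i of

        I_rep = -R_i (x_k - x_j) / |x_k - x_j|^2      (always, if enabled)
        I_attr = (x_k - x_j) / |x_k - x_j|            (optional, default off)

    Coincident pairs (distance < 1e-9 m) are capped at magnitude R_i/1e-9
    with a randomised push direction (``rng`` needed only then).
    Returns per-agent velocity contributions ``(ix, iy)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("need at least one agent")
    zx = np.zeros(n)
    if n == 1 or not (params.repulsion or params.attraction):
        return zx, zx.copy()
    dx = x[None, :] - x[:, None]   # [j, k] = x_k - x_j
    dy = y[None, :] - y[:, None]
    d2 = dx * dx + dy * dy
    np.fill_diagonal(d2, np.inf)
    if not (d2 <= params.R_i * params.R_i).any():  # dilute swarm fast path
        return zx, zx.copy()
    d = np.sqrt(d2)
    near = d < COINCIDENT_EPS
    np.fill_diagonal(near, False)
    if near.any():
        if rng is None:
            rng = np.random.default_rng(0)
        ang = rng.uniform(-np.pi, np.pi, size=int(near.sum()))
        dcap = COINCIDENT_EPS
        dx[near] = dcap * np.cos(ang)
        dy[near] = dcap * np.sin(ang)
        d[near] = dcap
    neighbor = (d <= params.R_i)
    np.fill_diagonal(neighbor, False)
    n_j = neighbor.sum(axis=1)
    d_safe = np.where(neighbor, d, 1.0)
    contrib_x = np.zeros_like(d)
    contrib_y = np.zeros_like(d)
    if params.repulsion:
        w = -params.R_i / d_safe**2
        contrib_x += w * dx
        contrib_y += w * dy
    if params.attraction:
        contrib_x += dx / d_safe
        contrib_y += dy / d_safe
    contrib_x = np.where(neighbor, contrib_x, 0.0)
    contrib_y = np.where(neighbor, contrib_y, 0.0)
    denom = np.maximum(n_j, 1)
    return contrib_x.sum(axis=1) / denom, contrib_y.sum(axis=1) / denom


def wall_force(x, y, geometry: TankGeometry, R_w: float):
    """Per-axis soft-sphere wall repulsion.

    Each of the four walls closer than ``R_w`` along its normal contributes
    an inward velocity of magnitude ``R_w / d`` (same 1/d law as the
    agent-agent repulsion).  Positions outside the tank raise ValueError.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(geometry.contains(x, y)):
        raise ValueError("agent position outside the tank")
    eps = COINCIDENT_EPS
    d_left = np.maximum(x - geometry.x_min, eps)
    d_right = np.maximum(geometry.x_max - x, eps)
    d_bot = np.maximum(y - geometry.y_min, eps)
    d_top = np.maximum(geometry.y_max - y, eps)
    fx = np.where(d_left <= R_w, R_w / d_left, 0.0) - np.where(d_right <= R_w, R_w / d_right, 0.0)
    fy = np.where(d_bot <= R_w, R_w / d_bot, 0.0) - np.where(d_top <= R_w, R_w / d_top, 0.0)
    return fx, fy


def positional_rhs(x, y, theta, phi, A, env, geometry: TankGeometry,
                   params: ModelParams, rng: np.random.Generator | None = None):
    """dx/dt = U + V(theta, phi, |U|, A) + I(x) + F_ext.

    ``env`` must provide arrays ``Ux, Uy``.  Tracer configurations fall out
    of the toggles: ``active=False, repulsion=False`` gives pure advection
    plus wall confinement; adding ``repulsion=True`` the repulsive tracer.
    """
    u_mag = np.hypot(env.Ux, env.Uy)
    ax, ay = active_velocity(theta, phi, u_mag, A, params)
    ix, iy = pairwise_interaction(x, y, params, rng)
    wx, wy = wall_force(x, y, geometry, params.R_w)
    return env.Ux + ax + ix + wx, env.Uy + ay + iy + wy
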