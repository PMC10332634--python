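"""Unit and property tests for the agent response functions and RHS terms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp

from medusim import agents as ag
from medusim.agents import ModelParams
from medusim.geometry import TankGeometry


# ---------------------------------------------------------------------------
# response function and parametric switches
# ---------------------------------------------------------------------------

class TestResponse:
    @pytest.mark.parametrize("a,b,s,expected", [
        (1.0, 0.05, 0.3, 0.3 / 0.35),     # 86% weakening point
        (1.0, 0.5, 0.3, 0.375),           # 38% weakening point
        (1.0, 0.3, 0.0, 0.0),
        (2.5, 1.0, 1e12, 2.5),            # saturation (to 1e-9 relative)
    ])
    def test_values(self, a, b, s, expected):
        assert ag.response(a, b, s) == pytest.approx(expected, rel=1e-9)

    def test_rejects_nonpositive_halfsaturation(self):
        with pytest.raises(ValueError):
            ag.response(1.0, 0.0, 0.5)

    @given(st.floats(0.01, 10), st.floats(0, 100), st.floats(0, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, b, s1, s2):
        lo, hi = sorted([s1, s2])
        r_lo, r_hi = ag.response(1.0, b, lo), ag.response(1.0, b, hi)
        assert 0 <= r_lo <= r_hi < 1.0


class TestParametricSwitches:
    def test_inactive_state(self):
        p = ModelParams()
        eps_u, eps_c, eps_f = ag.coupling_strengths(0.0, 0.0, p)
        assert eps_u == pytest.approx(p.eps_U0)
        assert eps_c == pytest.approx(p.eps_C0)
        assert eps_f == 0.0

    @pytest.mark.parametrize("f_u,percent", [(0.05, 86), (0.01, 97), (0.1, 75), (0.5, 38)])
    def test_counter_current_weakening(self, f_u, percent):
        """Prey at 0.3 F_0 weakens the rheotaxis coupling by the printed percent."""
        p = ModelParams(f_U=f_u)
        eps_u, _, _ = ag.coupling_strengths(0.0, 0.3, p)
        weakening = 100.0 * (1.0 - eps_u / p.eps_U0)
        assert int(np.floor(round(weakening, 9) + 0.5)) == percent

    def test_prey_coupling_nonmonotone(self):
        """eps_F(A) rises from 0, peaks, and decays toward 0 (greedy shutoff)."""
        p = ModelParams()
        grid = np.geomspace(1e-3, 1e5, 400)
        _, _, eps_f = ag.coupling_strengths(grid, 0.0, p)
        k = int(np.argmax(eps_f))
        assert 0 < k < grid.size - 1
        assert eps_f[0] < eps_f[k] and eps_f[-1] < 0.05 * eps_f[k]
        assert np.all(np.diff(eps_f[: k + 1]) >= 0)
        assert np.all(np.diff(eps_f[k:]) <= 0)


# ---------------------------------------------------------------------------
# activity, frequency, noise
# ---------------------------------------------------------------------------

class TestActivity:
    def test_swimming_away_pure_decay(self):
        p = ModelParams()
        rhs = ag.activity_rhs(np.pi, 2.0, 5.0, 0.0, True, p)
        assert rhs == pytest.approx(-p.lambda_A * 2.0)

    def test_fixed_point(self):
        """Aligned swimming in a constant gradient saturates at A* = g/lambda_A."""
        p = ModelParams()
        g = 0.02
        a_star = g / p.lambda_A
        assert ag.activity_rhs(0.3, a_star, g, 0.3, True, p) == pytest.approx(0.0)

    def test_zero_input(self):
        assert ag.activity_rhs(0.1, 0.0, 0.0, 0.0, False, ModelParams()) == 0.0

    def test_nonnegative_under_heun(self, rng):
        """A(0) >= 0 stays non-negative when stepped at dt <= 0.01 s."""
        p = ModelParams()
        a = 0.0
        dt = 0.01
        for k in range(2000):
            grad = 0.05 if (k // 200) % 2 == 0 else 0.0  # intermittent drive
            k1 = ag.activity_rhs(0.0, a, grad, 0.0, True, p)
            k2 = ag.activity_rhs(0.0, a + dt * k1, grad, 0.0, True, p)
            a = a + 0.5 * dt * (k1 + k2)
            assert a >= 0.0


class TestBellFrequency:
    def test_inactive(self):
        assert ag.bell_frequency(0.0, ModelParams()) == pytest.approx(1.2)

    def test_saturation(self):
        p = ModelParams()
        assert ag.bell_frequency(1e12, p) == pytest.approx(p.omega0 * 1.75, rel=1e-9)

    def test_halfway(self):
        p = ModelParams()
        # R(f, f, f) = f/2
        assert ag.bell_frequency(p.f_phi, p) == pytest.approx(1.2 * 1.375)


class TestAngularNoise:
    def test_deterministic_decay(self):
        """With D = 0 the drift decays exponentially at rate lambda_theta."""
        p = ModelParams(D0=0.0, lambda_theta=2.0)
        rng = np.random.default_rng(0)
        L = np.array([1.0])
        dt = 0.001
        for _ in range(1000):
            L = ag.angular_noise_step(L, 0.0, dt, rng, p)
        assert L[0] == pytest.approx(np.exp(-2.0), rel=1e-4)

    def test_activity_raises_variance(self):
        p = ModelParams()
        assert ag.noise_intensity(1e12, p) / ag.noise_intensity(0.0, p) == pytest.approx(1.75)

    def test_stationary_std(self, rng):
        """Empirical stationary std matches sqrt(D/lambda) for the default rate."""
        p = ModelParams(lambda_theta=5.0, D0=0.1)
        L = np.zeros(256)
        dt = 0.01
        samples = []
        for k in range(4000):
            L = ag.angular_noise_step(L, 0.0, dt, rng, p)
            if k > 400:
                samples.append(L.copy())
        std = np.concatenate(samples).std()
        assert std == pytest.approx(ag.ou_stationary_std(0.1, 5.0), rel=0.03)


# ---------------------------------------------------------------------------
# orientation dynamics
# ---------------------------------------------------------------------------

def _orientation_ode(eps, deltas):
    ok = (True, True, True)

    def rhs(_, th):
        return ag.orientation_rhs(th, 0.0, eps, deltas, ok, ModelParams())

    return rhs


def _stable_roots_bruteforce(eps, deltas, n=20001):
    """Independent oracle: dense scan for sign changes with negative slope."""
    th = np.linspace(-np.pi, np.pi, n)
    ok = (np.ones(n, bool),) * 3
    g = ag.orientation_rhs(th, np.zeros(n), eps, deltas, ok, ModelParams())
    roots = []
    for i in range(n - 1):
        if g[i] == 0.0 or g[i] * g[i + 1] < 0:
            if g[i] > g[i + 1]:  # descending crossing = stable
                roots.append(th[i] + (th[i + 1] - th[i]) * g[i] / (g[i] - g[i + 1]))
    return np.asarray(roots)


class TestOrientation:
    def test_counter_current_fixed_point(self):
        """Sole flow coupling: stable orientation is against the flow."""
        delta_u = np.pi / 8
        eps = (0.8, 0.0, 0.0)
        deltas = (delta_u, 0.0, 0.0)
        for th0 in np.linspace(-np.pi + 0.3, np.pi, 7):
            if abs(ag.wrap_angle(th0 - delta_u)) < 1e-6:
                continue  # unstable point itself
            sol = solve_ivp(_orientation_ode(eps, deltas), (0, 200.0), [th0], rtol=1e-8)
            final = ag.wrap_angle(sol.y[0, -1] - (delta_u + np.pi))
            assert abs(final) < 1e-3

    def test_prey_dominated_unique_orientation(self):
        """Mixed couplings with dominant prey term: one stable point near delta_F."""
        eps = (0.1, 0.2, 0.7)
        deltas = (np.pi / 8, 6 * np.pi / 5, ag.wrap_angle(1.7 * np.pi))
        roots = _stable_roots_bruteforce(eps, deltas)
        assert roots.size == 1
        assert abs(ag.wrap_angle(roots[0] - deltas[2])) < 0.5
        sol = solve_ivp(_orientation_ode(eps, deltas), (0, 300.0), [0.1], rtol=1e-8)
        assert abs(ag.wrap_angle(sol.y[0, -1] - roots[0])) < 1e-3

    @given(st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_converges_to_a_stable_root(self, seed):
        """Integrated orientation always lands on a brute-force stable root."""
        r = np.random.default_rng(seed)
        eps = tuple(r.uniform(0.05, 1.0, 3))
        deltas = tuple(r.uniform(-np.pi, np.pi, 3))
        roots = _stable_roots_bruteforce(eps, deltas)
        assert roots.size >= 1
        th0 = r.uniform(-np.pi, np.pi)
        sol = solve_ivp(_orientation_ode(eps, deltas), (0, 500.0), [th0], rtol=1e-9)
        final = ag.wrap_angle(sol.y[0, -1])
        dist = np.abs(ag.wrap_angle(final - roots))
        assert dist.min() < 1e-2


# ---------------------------------------------------------------------------
# bell pulsation and propulsion
# ---------------------------------------------------------------------------

class TestBell:
    def test_beta_peak(self):
        assert ag.bell_beta(0.0, 5.0) == 1.0

    def test_beta_trough(self):
        assert ag.bell_beta(np.pi, 5.0) == pytest.approx(np.exp(-10.0))

    @pytest.mark.parametrize("J", [0.5, 1.0, 5.0])
    def test_period_average_closed_form(self, J):
        """Quadrature over one period matches exp(-J) I0(J) to 1e-6."""
        val, _ = quad(lambda p: ag.bell_beta(p, J), 0, 2 * np.pi)
        assert val / (2 * np.pi) == pytest.approx(ag.mean_bell_factor(J), abs=1e-6)

    def test_mean_factor_near_half(self):
        assert round(ag.mean_bell_factor(1.0), 2) == 0.47


class TestActiveVelocity:
    def test_calibrated_mean_speed(self):
        """Time-averaged speed at the channel inflow magnitude is ~0.087 m/s."""
        p = ModelParams()
        phi = np.linspace(0, 2 * np.pi, 20001)[:-1]
        speed = ag.swim_speed(phi, 0.045, 0.0, p).mean()
        assert speed == pytest.approx(0.087, rel=0.02)

    def test_pure_tracer(self):
        p = ModelParams(V0=0.0, Va=0.0)
        vx, vy = ag.active_velocity(0.3, 0.1, 0.5, 0.0, p)
        assert vx == 0.0 and vy == 0.0

    def test_still_water_mean(self):
        p = ModelParams()
        phi = np.linspace(0, 2 * np.pi, 20001)[:-1]
        speed = ag.swim_speed(phi, 0.0, 0.0, p).mean()
        assert speed == pytest.approx(p.V0 * ag.mean_bell_factor(1.0), rel=1e-4)


# ---------------------------------------------------------------------------
# interactions
# ---------------------------------------------------------------------------

class TestPairwise:
    def test_cutoff_boundary_magnitude(self):
        p = ModelParams(R_i=0.1)
        ix, iy = ag.pairwise_interaction([0.0, 0.1], [0.0, 0.0], p)
        assert ix[0] == pytest.approx(-1.0) and ix[1] == pytest.approx(1.0)
        assert iy == pytest.approx([0.0, 0.0])

    def test_inverse_distance_law(self):
        p = ModelParams(R_i=0.1)
        ix, _ = ag.pairwise_interaction([0.0, 0.05], [0.0, 0.0], p)
        assert ix[0] == pytest.approx(-2.0)

    def test_isolated_agent(self):
        p = ModelParams(R_i=0.1)
        ix, iy = ag.pairwise_interaction([0.0, 5.0], [0.0, 0.0], p)
        assert np.all(ix == 0.0) and np.all(iy == 0.0)

    def test_coincident_cap(self, rng):
        p = ModelParams(R_i=0.1)
        ix, iy = ag.pairwise_interaction([0.0, 0.0], [0.0, 0.0], p, rng)
        mag = np.hypot(ix, iy)
        assert mag == pytest.approx([p.R_i / 1e-9] * 2, rel=1e-6)

    @given(st.floats(0.01, 1.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_outward_and_decreasing(self, frac):
        """Repulsion points apart and weakens with distance on (0, R_i]."""
        p = ModelParams(R_i=0.5)
        d = frac * p.R_i
        ix, _ = ag.pairwise_interaction([0.0, d], [0.0, 0.0], p)
        assert ix[0] < 0 < ix[1]
        ix2, _ = ag.pairwise_interaction([0.0, d / 2], [0.0, 0.0], p)
        assert abs(ix2[0]) > abs(ix[0])


class TestWallForce:
    def test_cutoff_boundary(self):
        g = TankGeometry(0, 2, 0, 2, 17, 17, "cavity")
        fx, fy = ag.wall_force(0.1, 1.0, g, 0.1)
        assert fx == pytest.approx(1.0) and fy == 0.0

    def test_corner_superposition(self):
        g = TankGeometry(0, 2, 0, 2, 17, 17, "cavity")
        fx, fy = ag.wall_force(0.05, 0.025, g, 0.1)
        assert fx == pytest.approx(0.1 / 0.05) and fy == pytest.approx(0.1 / 0.025)

    def test_interior_zero(self):
        g = TankGeometry(0, 2, 0, 2, 17, 17, "cavity")
        fx, fy = ag.wall_force(1.0, 1.0, g, 0.1)
        assert fx == 0.0 and fy == 0.0

    def test_outside_raises(self):
        g = TankGeometry(0, 2, 0, 2, 17, 17, "cavity")
        with pytest.raises(ValueError):
            ag.wall_force(-0.1, 1.0, g, 0.1)


class TestPositionalRHS:
    def test_passive_uniform_advection(self):
        from types import SimpleNamespace

        g = TankGeometry(0, 10, 0, 10, 81, 81, "cavity")
        p = ModelParams(active=False, repulsion=False)
        env = SimpleNamespace(Ux=np.full(3, 0.2), Uy=np.full(3, -0.1))
        vx, vy = ag.positional_rhs(np.array([3.0, 5.0, 7.0]), np.full(3, 5.0),
                                   np.zeros(3), np.zeros(3), np.zeros(3), env, g, p)
        assert vx == pytest.approx([0.2] * 3) and vy == pytest.approx([-0.1] * 3)

    def test_everything_off_is_stationary(self):
        from types import SimpleNamespace

        g = TankGeometry(0, 10, 0, 10, 81, 81, "cavity")
        p = ModelParams(active=False, repulsion=False)
        env = SimpleNamespace(Ux=np.zeros(1), Uy=np.zeros(1))
        vx, vy = ag.positional_rhs(np.array([5.0]), np.array([5.0]),
                                   np.zeros(1), np.zeros(1), np.zeros(1), env, g, p)
        assert vx == 0.0 and vy == 0.0
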