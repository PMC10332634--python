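"""The four tank experiments and their parameter scans.

Every pipeline assembles a :class:`~medusim.simulation.RunConfig`, runs K
repetitions with seeds spawned from one master seed, and reduces the
trajectory records to the swarm statistics of :mod:`medusim.metrics`.
Scans default to frozen analytic flow replay at dt = 0.005 s with K = 4
repetitions (a documented speed/accuracy trade-off; the flow couples
one-way, so replaying a steady profile is exact for steady scenarios);
``flow_mode="live"``, ``dt=0.001`` and ``K=16`` restore full fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics as mt
from .agents import ModelParams
from .simulation import RunConfig, run_ensemble

#: still-water swimming speed used to normalise the counter-current scan [m s^-1]
REFERENCE_STILL_SPEED = 0.067

MECHANISMS = ("A", "A+B", "A+C", "A+B+C", "D")


@dataclass
class ScanSpec:
    """A parameter scan: experiment tag, swept grids, replication, output."""

    experiment: str
    grids: dict = field(default_factory=dict)
    n_runs: int = 4
    seed: int = 0
    out: str | None = None


def default_scan_grids(experiment: str) -> dict:
    """The printed scan sets for each experiment."""
    eps_grid = list(0.005 * 2.0 ** np.arange(8)) + [1.0]
    if experiment == "counter_current":
        return {"eps_U0": eps_grid, "lambda_theta": [0.2, 1.0, 5.0]}
    if experiment == "turbulence_avoidance":
        return {"eps_U0": [0.005, 0.16, 1.0], "eps_C0": eps_grid}
    if experiment == "wall_effects":
        return {"n_agents": [8, 32, 128, 512], "R_i": [0.1, 0.5, 1.0]}
    if experiment == "foraging":
        # the eps_F0 grid is log-spaced over the explored range
        return {"eps_F0": list(np.geomspace(0.04, 0.64, 5)),
                "f_U": [0.025, 0.05, 0.075, 0.1, 0.5]}
    raise ValueError(f"unknown experiment {experiment!r}")


# ---------------------------------------------------------------------------
# counter-current swimming (channel)
# ---------------------------------------------------------------------------

def counter_current_params(eps_U0: float = 0.16, lambda_theta: float = 5.0,
                           D0: float = 0.1) -> ModelParams:
    """Reduced counter-current model: advection + propulsion + soft-core
    repulsion + walls, orientation from colored noise and the
    counter-current coupling only (no activity, vorticity or prey terms)."""
    return ModelParams(
        eps_U0=eps_U0, lambda_theta=lambda_theta, D0=D0,
        turbulence_avoidance=False, prey_orientation=False,
        activity_dynamics=False, freq_response=False, noise_response=False,
        flow_decoupling=False, vorticity_decoupling=False,
        speed_activity_response=False,
    )


def counter_current_fraction(eps_U0: float = 0.16, lambda_theta: float = 5.0,
                             seed: int = 0, n_agents: int = 128,
                             total_time: float = 300.0, dt: float = 0.005,
                             n_runs: int = 4, flow_mode: str = "analytic") -> dict:
    """Fraction of still-water swimming speed achieved against the channel flow.

    For each run, the ensemble mean of the agent velocity relative to the
    local flow, m(t) = mean_j(xdot_j - U_j), is formed at every record time;
    |m(t)| is averaged over the central two-thirds of the run and divided by
    the 0.067 m s^-1 still-water reference.  Returns per-run fractions and
    their mean.
    """
    cfg = RunConfig(
        scenario="channel",
        model=counter_current_params(eps_U0, lambda_theta),
        n_agents=n_agents, n_runs=n_runs, dt_agent=dt,
        total_time=total_time, seed=seed, flow_mode=flow_mode,
    )
    results = run_ensemble(cfg)
    fractions = []
    for res in results:
        rec = res.record
        t = rec.times
        window = (t >= total_time / 6.0) & (t <= 5.0 * total_time / 6.0)
        mx = (rec["vx"] - rec["Ux"]).mean(axis=1)
        my = (rec["vy"] - rec["Uy"]).mean(axis=1)
        speed = np.hypot(mx, my)[window].mean()
        fractions.append(speed / REFERENCE_STILL_SPEED)
    fractions = np.asarray(fractions)
    return {"fractions": fractions, "mean": float(fractions.mean()),
            "eps_U0": eps_U0, "lambda_theta": lambda_theta}


def run_counter_current(spec: ScanSpec | None = None, **kwargs) -> pd.DataFrame:
    """Speed-fraction curve over (eps_U0, lambda_theta)."""
    spec = spec or ScanSpec("counter_current")
    grids = spec.grids or default_scan_grids("counter_current")
    rows = []
    for lam in grids["lambda_theta"]:
        for eps in grids["eps_U0"]:
            out = counter_current_fraction(eps, lam, seed=spec.seed,
                                           n_runs=spec.n_runs, **kwargs)
            rows.append({"eps_U0": eps, "lambda_theta": lam,
                         "speed_fraction": out["mean"],
                         "speed_fraction_std": float(out["fractions"].std())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# wall effects (cavity, tracer ensembles)
# ---------------------------------------------------------------------------

def run_wall_effects(n_agents=(32, 128), interaction_radii=(0.1, 0.5), seed: int = 0,
                     total_time: float = 150.0, n_runs: int = 2, dt: float = 0.005,
                     wall_radius: float = 0.5, burn_in: float = 50.0,
                     flow_mode: str = "analytic") -> pd.DataFrame:
    """Delta Corr_V,U and Delta Hex_6 between repulsive and passive tracers.

    Both ensembles share initial positions and the frozen cavity flow; the
    wall interaction distance is 0.5 m for this experiment.  Statistics are
    time averages of the K-run double averages after the transient.
    """
    rows = []
    for n in n_agents:
        for ri in interaction_radii:
            model = ModelParams(R_i=ri, R_w=wall_radius, active=False,
                                repulsion=True, activity_dynamics=False)
            cfg = RunConfig(scenario="cavity", model=model, n_agents=n,
                            n_runs=n_runs, dt_agent=dt, total_time=total_time,
                            seed=seed, twin_mode="passive", flow_mode=flow_mode)
            results = run_ensemble(cfg)
            times = results[0].record.times
            window = times >= burn_in
            d_corr, d_hex = [], []
            for res in results:
                ra, rp = res.record, res.twin
                corr_a = np.array([mt.velocity_correlation(ra["vx"][i], ra["vy"][i],
                                                           ra["Ux"][i], ra["Uy"][i])
                                   for i in range(times.size)])
                corr_p = np.array([mt.velocity_correlation(rp["vx"][i], rp["vy"][i],
                                                           rp["Ux"][i], rp["Uy"][i])
                                   for i in range(times.size)])
                hex_a = np.array([mt.hex_order(ra["x"][i], ra["y"][i], 6)
                                  for i in range(times.size)])
                hex_p = np.array([mt.hex_order(rp["x"][i], rp["y"][i], 6)
                                  for i in range(times.size)])
                d_corr.append(mt.delta_series(corr_a, corr_p))
                d_hex.append(mt.delta_series(hex_a, hex_p))
            dc = mt.double_average(times, np.asarray(d_corr)).double_avg
            dh = mt.double_average(times, np.asarray(d_hex)).double_avg
            rows.append({"n_agents": n, "R_i": ri,
                         "delta_corr": float(np.nanmean(dc[window])),
                         "delta_hex6": float(np.nanmean(dh[window]))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# turbulence avoidance (cavity)
# ---------------------------------------------------------------------------

def turbulence_params(eps_U0: float = 0.16, eps_C0: float = 0.08) -> ModelParams:
    """Counter-current + turbulence-avoidance orientation, no activity/prey."""
    return ModelParams(
        eps_U0=eps_U0, eps_C0=eps_C0,
        counter_current=eps_U0 > 0, turbulence_avoidance=True,
        prey_orientation=False, activity_dynamics=False,
        freq_response=False, noise_response=False,
        flow_decoupling=False, vorticity_decoupling=False,
        speed_activity_response=False,
    )


def run_turbulence_avoidance(eps_U0_grid=(0.005, 0.16), eps_C0_grid=(0.01, 0.16),
                             seed: int = 0, n_agents: int = 128, n_runs: int = 2,
                             total_time: float = 900.0, dt: float = 0.005,
                             burn_in: float = 50.0, structure_window: float = 300.0,
                             flow_mode: str = "analytic",
                             hex_neighbors: int = 12) -> pd.DataFrame:
    """Baseline turbulence fraction P_min(|C|), Delta Hex_12 and Delta Sigma.

    P(|C|) compares active agents against the passive twin via the
    indication number with the twin's mean |C| as threshold; the baseline
    average uses the spike filter (samples below 0.9 P_tilde + 0.1 P_hat)
    after the burn-in.  Structure metrics average over the final
    ``structure_window`` seconds.
    """
    rows = []
    for eps_u in eps_U0_grid:
        for eps_c in eps_C0_grid:
            cfg = RunConfig(scenario="cavity", model=turbulence_params(eps_u, eps_c),
                            n_agents=n_agents, n_runs=n_runs, dt_agent=dt,
                            total_time=total_time, seed=seed, twin_mode="passive",
                            flow_mode=flow_mode)
            results = run_ensemble(cfg)
            times = results[0].record.times
            tail = times >= (times[-1] - structure_window)
            p_series, d_hex, d_sig = [], [], []
            for res in results:
                ra, rp = res.record, res.twin
                p = np.array([mt.turbulence_fraction(ra["absC"][i], rp["absC"][i])
                              for i in range(times.size)])
                p_series.append(p)
                hex_a = np.array([mt.hex_order(ra["x"][i], ra["y"][i], hex_neighbors)
                                  for i in range(times.size)])
                hex_p = np.array([mt.hex_order(rp["x"][i], rp["y"][i], hex_neighbors)
                                  for i in range(times.size)])
                sig_a = np.array([mt.spread(ra["x"][i], ra["y"][i], ra["x"][0], ra["y"][0])
                                  for i in range(times.size)])
                sig_p = np.array([mt.spread(rp["x"][i], rp["y"][i], rp["x"][0], rp["y"][0])
                                  for i in range(times.size)])
                d_hex.append(mt.delta_series(hex_a, hex_p))
                d_sig.append(mt.delta_series(sig_a, sig_p))
            p_avg = mt.double_average(times, np.asarray(p_series)).double_avg
            dh = mt.double_average(times, np.asarray(d_hex)).double_avg
            ds = mt.double_average(times, np.asarray(d_sig)).double_avg
            rows.append({
                "eps_U0": eps_u, "eps_C0": eps_c,
                "P_min": mt.baseline_fraction(p_avg, times, burn_in),
                "delta_hex": float(np.nanmean(dh[tail])),
                "delta_sigma": float(np.nanmean(ds[tail])),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# foraging (double gyre)
# ---------------------------------------------------------------------------

def mechanism_params(mechanism: str = "D", eps_F0: float | None = None,
                     f_U: float | None = None, f_F: float | None = None) -> ModelParams:
    """Response-mechanism subsets of the full foraging model.

    A      frequency omega(A) and noise D(A) responses only
    A+B    adds the eps_C(A) decoupling with an immediate response (f_C = 0.02)
    A+C    adds the speed response V(|U| + A)
    A+B+C  both
    D      the full model at the printed defaults
    """
    if mechanism not in MECHANISMS:
        raise ValueError(f"unknown mechanism {mechanism!r}; expected one of {MECHANISMS}")
    if mechanism == "D":
        p = ModelParams()
    else:
        p = ModelParams(prey_orientation=False, flow_decoupling=False,
                        vorticity_decoupling=False, speed_activity_response=False)
        if "B" in mechanism:
            p = replace(p, vorticity_decoupling=True, f_C=0.02)
        if "C" in mechanism:
            p = replace(p, speed_activity_response=True)
    overrides = {}
    if eps_F0 is not None:
        overrides["eps_F0"] = eps_F0
    if f_U is not None:
        overrides["f_U"] = f_U
    if f_F is not None:
        overrides["f_F"] = f_F
    return replace(p, **overrides) if overrides else p


def run_foraging(mechanisms=MECHANISMS, seed: int = 0, n_agents: int = 128,
                 n_runs: int = 2, total_time: float = 900.0, dt: float = 0.005,
                 eps_F0: float | None = None, f_U: float | None = None,
                 f_F: float | None = None, flow_mode: str = "analytic") -> pd.DataFrame:
    """Crossing fraction <P(x)> and left-gyre spread <Sigma_0> per mechanism set.

    Agents start in the right gyre (x > 0), prey saturates the left gyre;
    the passive twin provides the crossing-number denominator.
    """
    rows = []
    for mech in mechanisms:
        model = mechanism_params(mech, eps_F0=eps_F0, f_U=f_U, f_F=f_F)
        cfg = RunConfig(scenario="double_gyre", model=model, n_agents=n_agents,
                        n_runs=n_runs, dt_agent=dt, total_time=total_time,
                        seed=seed, twin_mode="passive", prey_enabled=True,
                        flow_mode=flow_mode)
        results = run_ensemble(cfg)
        times = results[0].record.times
        p_series, s_series = [], []
        for res in results:
            ra, rp = res.record, res.twin
            p = np.array([mt.crossing_fraction(ra["x"][i], rp["x"][i])
                          for i in range(times.size)])
            sig0 = np.array([mt.left_gyre_spread(ra, i) for i in range(times.size)])
            p_series.append(p)
            s_series.append(sig0)
        p_avg = mt.double_average(times, np.asarray(p_series)).double_avg
        rows.append({
            "mechanism": mech,
            "crossing_fraction": float(np.nanmean(p_avg)),
            "left_spread": float(np.nanmean(np.asarray(s_series))),
        })
    return pd.DataFrame(rows)
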