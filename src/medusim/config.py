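"""Configuration files and output writers.

Configs are plain-text YAML with four blocks (``scenario``, ``fluid``,
``agent``, ``run``) plus a free-form ``experiment`` block for scans.  Keys
carry their units in the name (e.g. ``lambda_theta_per_s``) to prevent unit
drift; unknown keys are rejected; an empty file yields the full printed
default parameter set.  Every output file records the config hash and seed
so a run can be reproduced from any one of its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .agents import ModelParams
from .fluid import FluidParams
from .simulation import RunConfig

# unit-suffixed config key -> dataclass field
FLUID_KEYS = {
    "density_kg_per_m3": "rho",
    "viscosity_Ns_per_m2": "mu",
    "dt_fluid_s": "dt",
    "sor_omega": "sor_omega",
    "sor_tol": "sor_tol",
    "sor_max_iter": "sor_max_iter",
    "lid_speed_m_per_s": "lid_speed",
    "inflow_peak_m_per_s": "inflow_peak",
}

AGENT_KEYS = {
    "R_i_m": "R_i",
    "R_w_m": "R_w",
    "lambda_theta_per_s": "lambda_theta",
    "D0_rad2_per_s3": "D0",
    "V0_m_per_s": "V0",
    "Va_m_per_s": "Va",
    "Vb_m_per_s": "Vb",
    "J": "J",
    "eps_U0_rad_per_s": "eps_U0",
    "eps_C0_rad_per_s": "eps_C0",
    "eps_F0_rad_per_s": "eps_F0",
    "omega0_rad_per_s": "omega0",
    "lambda_A_per_s": "lambda_A",
    "f_phi": "f_phi",
    "f_theta": "f_theta",
    "f_U_F0": "f_U",
    "f_C": "f_C",
    "f_F": "f_F",
    "f_g": "f_g",
}
AGENT_TOGGLES = (
    "active", "repulsion", "attraction", "phase_coupling", "counter_current",
    "turbulence_avoidance", "prey_orientation", "activity_dynamics",
    "freq_response", "noise_response", "flow_decoupling",
    "vorticity_decoupling", "speed_activity_response",
)

RUN_KEYS = {
    "n_agents": "n_agents",
    "n_runs": "n_runs",
    "dt_agent_s": "dt_agent",
    "record_interval_s": "record_interval",
    "total_time_s": "total_time",
    "seed": "seed",
    "flow_mode": "flow_mode",
    "twin_mode": "twin_mode",
    "prey_enabled": "prey_enabled",
    "analytic_peak_speed_m_per_s": "analytic_peak_speed",
    "init_margin_m": "init_margin",
}


class ConfigError(ValueError):
    pass


def _pick(block: dict, mapping: dict, toggles=()) -> dict:
    out = {}
    unknown = []
    for key, value in (block or {}).items():
        if key in mapping:
            out[mapping[key]] = value
        elif key in toggles:
            out[key] = bool(value)
        else:
            unknown.append(key)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return out


def config_from_dict(raw: dict | None) -> RunConfig:
    raw = raw or {}
    known_blocks = {"scenario", "fluid", "agent", "run", "experiment"}
    extra = set(raw) - known_blocks
    if extra:
        raise ConfigError(f"unknown config blocks: {sorted(extra)}")
    scenario_block = raw.get("scenario") or {}
    bad = set(scenario_block) - {"name"}
    if bad:
        raise ConfigError(f"unknown config keys: {sorted(bad)}")
    scenario = scenario_block.get("name", "cavity")
    fluid = FluidParams(**_pick(raw.get("fluid"), FLUID_KEYS))
    model = ModelParams(**_pick(raw.get("agent"), AGENT_KEYS, AGENT_TOGGLES))
    run_kwargs = _pick(raw.get("run"), RUN_KEYS)
    return RunConfig(scenario=scenario, model=model, fluid=fluid, **run_kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML config; an empty file gives all defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is not None and not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    return config_from_dict(raw)


def config_to_dict(config: RunConfig) -> dict:
    """Lossless echo of a RunConfig using the unit-suffixed key names."""
    inv_fluid = {v: k for k, v in FLUID_KEYS.items()}
    inv_agent = {v: k for k, v in AGENT_KEYS.items()}
    inv_run = {v: k for k, v in RUN_KEYS.items()}
    fluid = {inv_fluid[f.name]: getattr(config.fluid, f.name)
             for f in dataclasses.fields(config.fluid)}
    agent = {}
    for f in dataclasses.fields(config.model):
        if f.name in inv_agent:
            agent[inv_agent[f.name]] = getattr(config.model, f.name)
        elif f.name in AGENT_TOGGLES:
            agent[f.name] = getattr(config.model, f.name)
    run_block = {cfg_key: getattr(config, field_name)
                 for field_name, cfg_key in inv_run.items()}
    return {"scenario": {"name": config.scenario}, "fluid": fluid,
            "agent": agent, "run": run_block}


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_outputs(results, out_dir: str | Path, config: RunConfig,
                  metrics_df=None, snapshot: bool = False) -> dict:
    """Write trajectories CSV, optional metrics CSV, and a summary JSON.

    ``results`` is a list of :class:`~medusim.simulation.SimulationResult`.
    Every file name is returned; the summary carries the full config echo,
    seed and config hash (enough to re-run the experiment).
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    frames = []
    for k, res in enumerate(results):
        df = res.record.to_dataframe()
        df.insert(0, "run", k)
        frames.append(df)
    traj_path = out_dir / "trajectories.csv"
    pd.concat(frames, ignore_index=True).to_csv(traj_path, index=False)
    written = {"trajectories": str(traj_path)}

    if metrics_df is not None:
        metrics_path = out_dir / "metrics.csv"
        metrics_df.to_csv(metrics_path, index=False)
        written["metrics"] = str(metrics_path)

    if snapshot and results and results[0].flow is not None:
        written["flow_snapshot"] = str(write_flow_snapshot(
            results[0].flow, out_dir / "flow_snapshot.nc"))

    summary = {"config": config_to_dict(config), "seed": config.seed,
               "config_hash": chash, "files": written}
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, default=float))
    written["summary"] = str(summary_path)
    return written


def write_flow_snapshot(flow, path: str | Path):
    """Flow snapshot as a NetCDF array container (variables u, v, p, time)."""
    import xarray as xr

    g = flow.geometry
    ds = xr.Dataset(
        {
            "u": (("x_face", "y_center"), flow.u),
            "v": (("x_center", "y_face"), flow.v),
            "p": (("x_center", "y_center"), flow.p),
        },
        coords={
            "x_face": g.x_nodes, "y_face": g.y_nodes,
            "x_center": g.x_centers, "y_center": g.y_centers,
        },
        attrs={"time": flow.time, "scenario": g.scenario},
    )
    ds.to_netcdf(path, engine="scipy")
    return path


def write_prey_snapshot(prey, path: str | Path):
    """Prey snapshot in the same array container (variable F, units F_0)."""
    import xarray as xr

    g = prey.geometry
    ds = xr.Dataset(
        {"F": (("x_center", "y_center"), prey.F)},
        coords={"x_center": g.x_centers, "y_center": g.y_centers},
        attrs={"diffusivity_m2_per_s": prey.diffusivity, "scenario": g.scenario},
    )
    ds.to_netcdf(path, engine="scipy")
    return path


def read_prey_snapshot(path: str | Path, geometry):
    import xarray as xr

    from .prey import PreyField

    with xr.open_dataset(path, engine="scipy") as ds:
        return PreyField(geometry, ds["F"].values.copy(),
                         float(ds.attrs.get("diffusivity_m2_per_s", 0.001)))


def read_flow_snapshot(path: str | Path, geometry):
    """Read a snapshot written by :func:`write_flow_snapshot`."""
    import xarray as xr

    from .fluid import FlowField

    with xr.open_dataset(path, engine="scipy") as ds:
        return FlowField(geometry, ds["u"].values.copy(), ds["v"].values.copy(),
                         ds["p"].values.copy(), float(ds.attrs.get("time", 0.0)))
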