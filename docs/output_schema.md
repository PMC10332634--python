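# Output file schema

## trajectories.csv

One row per (run, record time, agent).  Written by
`medusim.config.write_outputs`; units are SI, angles rad.

| column | meaning |
|---|---|
| run   | repetition index (0..K-1) |
| time  | record time [s] |
| agent | agent index (0..N-1) |
| x, y  | position [m] |
| theta | orientation [rad], wrapped to (-pi, pi] |
| phi   | bell phase [rad], mod 2 pi |
| A     | activity [-] |
| vx, vy | deterministic agent velocity at the record time [m s^-1] |
| Ux, Uy | flow velocity sampled at the agent [m s^-1] |
| absC  | absolute vorticity sampled at the agent [s^-1] |
| F     | prey concentration sampled at the agent [F_0] |

Tracer-twin records carry the subset (x, y, vx, vy, Ux, Uy, absC, F).

## metrics.csv

Tidy table keyed by the experiment's grid columns (e.g. `eps_U0`,
`lambda_theta`, `n_agents`, `R_i`, `mechanism`) with one column per
statistic: `speed_fraction`, `delta_corr`, `delta_hex6`, `P_min`,
`delta_hex`, `delta_sigma`, `crossing_fraction`, `left_spread`.
All fractions are in [0, 1]; Delta statistics are active minus passive.

## summary.json

`config` (full unit-keyed echo of the run configuration), `seed`,
`config_hash` (sha256 prefix of the canonical config), `files` (paths
written).  Any summary alone suffices to re-run its experiment.

## flow_snapshot.nc

NetCDF: `u(x_face, y_center)`, `v(x_center, y_face)`, `p(x_center,
y_center)` on the staggered grid, with coordinates in metres and attributes
`time`, `scenario`.
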