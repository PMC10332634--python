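# Methods

## The model

`medusim` simulates a swarm of N jellyfish-like agents in a 2D rectangular
tank.  Each agent `j` carries four dynamical variables: position
**x**_j = (x, y) [m], body orientation θ_j [rad], bell-pulsation phase
φ_j [rad] and a non-negative activity A_j (dimensionless excitation).  The
coupling to the environment is one-way: agents sample the flow field
**U**(**x**,t), the absolute vorticity |C| = |∂_x v − ∂_y u| (a local
turbulence proxy) and the prey concentration F (in units of the saturation
level F_0) by bilinear interpolation, but do not perturb the fluid.

Positional dynamics (over-damped):

    dx_j/dt = U_j + V(φ_j, |U_j|, A_j) ê(θ_j) + I(x_j) + F_ext

with propulsion speed

    V = (V_0 + R(V_a, V_b, |U_j| + A_j)) β(φ_j),      β(φ) = exp[J(cos φ − 1)],

soft-core repulsion I (per neighbour within R_i: −R_i Δx/|Δx|², averaged
over the N_j neighbours) and a per-axis wall repulsion of the same 1/d law
within R_w of a wall.  The activity is added raw to |U| in the speed
stimulus: the model treats A as commensurate with a speed — this is the
model's own unit convention, kept as printed.

Orientation:

    dθ_j/dt = L_j + ε_U sin(θ_j − δ_U) + ε_C sin(θ_j − δ_C) − ε_F sin(θ_j − δ_F)

where δ_U, δ_C, δ_F are the full-quadrant arctangent directions of the flow,
of the gradient of |C| and of the prey gradient.  The +sin terms make the
*anti-parallel* orientation stable (rheotaxis: swim against the flow; flee
rising turbulence); the −sin term stabilises swimming *up* the prey
gradient.  L_j is a colored (Ornstein–Uhlenbeck) angular drift,
dL = −λ_θ L dt + √(2D(A)) dW, with stationary std √(D/λ_θ).

Bell phase: dφ_j/dt = ω(A_j); the phase coupling H_j between bells is a
disabled stub (off by default, matching the model definition), as is the
attractive branch of the pairwise interaction.

Activity: dA_j/dt = −λ_A A_j + |∇F_j| · ½(|cos(θ_j − δ_F)| + cos(θ_j − δ_F));
the half-wave rectifier means only swimming within 90° of the ascending
prey gradient excites an agent.

All behavioural switches use one saturating response function
R(a, b, S) = aS/(b + S).  The parametric switches are

    ε_U(F) = ε_U,0 [1 − R(1, f_U, F)]            prey decouples rheotaxis
    ε_C(A) = ε_C,0 [1 − R(1, f_C, A)]            activity decouples avoidance
    ε_F(A) = ε_F,0 R(1, f_F, A)[1 − R(1, f_g, A)]  rises, then "greedy" shutoff
    ω(A)   = ω_0 [1 + R(f_φ, f_φ, A)]
    D(A)   = D_0 [1 + R(f_θ, f_θ, A)]

## Default parameters

All defaults are the model's published calibration: R_i = 0.1 m,
λ_θ = 5 s⁻¹, D_0 = 0.1 rad² s⁻³, V_0 = 0.15 m s⁻¹, V_a = 0.5 m s⁻¹,
V_b = 0.6 m s⁻¹, J = 1, ε_U,0 = 0.16 rad s⁻¹, ε_C,0 = 0.08 rad s⁻¹,
ε_F,0 = 0.16 rad s⁻¹, ω_0 = 1.2 rad s⁻¹, λ_A = 0.005 s⁻¹,
f_φ = f_θ = 0.75, f_U = 0.05 F_0, f_C = f_F = 0.2, f_g = 100, R_w = 0.1 m
(0.5 m in the wall-effects experiment).  Fluid: ρ = 1000 kg m⁻³, effective
μ = 0.4 N s m⁻², dt_fluid = 0.001 s; cavity lid and double-gyre walls move
at 0.4 m s⁻¹; channel peak inflow 0.045 m s⁻¹; prey diffusivity
D_F = 0.001 m² s⁻¹.  Ensembles default to N = 128 agents and K = 16
repetitions, recorded every 0.1 s.

Calibration identities the test-suite checks: the period average of β at
J = 1 is e⁻¹I₀(1) = 0.4658 (≈ 0.47); the mean propulsion speed at the
channel inflow magnitude is (0.15 + R(0.5, 0.6, 0.045))·0.4658 ≈ 0.086 m s⁻¹
(printed as 0.087); with ρ, μ above the channel Reynolds number
ρUL/μ = 1000·0.045·40/0.4 = 4500.  Note that the same formula gives 10⁴ for
the cavity (1000·0.4·10/0.4), not the 10⁵ sometimes quoted for it; the
package reports the formula value and takes no side on the discrepancy.

## Fluid solver

Incompressible Navier–Stokes on a staggered MAC grid: u on x-faces, v on
y-faces, p at cell centers, uniform spacing 0.125 m by default (channel
321×41 nodes over 40 m × 5 m; cavity 81×81 over 10 m × 10 m; double gyre
81×41 over 10 m × 5 m — the channel lattice is prescribed, the other two
keep the same spacing convention).  Advection and diffusion use
second-order central differences, stepped with Adams–Bashforth-2 (forward
Euler on the first step), followed by a Chorin projection.  The pressure
Poisson equation is solved by red-black SOR (relaxation 1.7, relative
residual tolerance 1e-4, at most 10 000 sweeps — unprescribed values chosen
for robustness); the all-Neumann problem is regularised by removing the
pressure mean every sweep.  Tangential wall conditions (moving lid / side
walls) enter through ghost layers; the channel imposes a parabolic inflow
at x = +20 m and a zero-gradient outflow corrected uniformly so outflow
flux equals inflow flux.  Stepping raises on advective CFL violation and
on SOR stall (with the residual).

Known limitation: central advection at the cavity's nominal Re = 10⁴ is
under-resolved on the default 81×81 grid (cell Péclet ≫ 2), so long live
cavity runs are not trustworthy at that resolution.  The experiments
therefore default to frozen analytic profiles (exact for the steady
channel; sinusoidal stream-function gyres for cavity and double gyre with
interior peak speed 0.1 m s⁻¹, a typical interior magnitude for a
0.4 m s⁻¹ driven wall).  These stream-function flows are discretely
divergence free by construction and reproduce the qualitative |C|
structure (quiet walls, vortical interior) but not the boundary-layer
filaments of the true cavity flow — green directional tests on them do not
establish the full cavity phenomenology.

## Prey field

F is advected and diffused in conservative flux form: van Leer-limited
MUSCL upwind reconstruction for advection, central diffusion, Heun
(SSP-RK2) in time, no-flux walls.  Total prey is conserved to round-off
and the scheme is positivity preserving within its stability bounds
(advective CFL 0.5, diffusive number 0.25; violations raise naming the
binding constraint).  The foraging initial condition saturates the left
half (F = F_0 for x < 0) with a tanh ramp ~2 cells wide to avoid
dispersive ringing — the smoothing width is a numerical choice, not part
of the stated scenario.  There is no prey consumption by agents.  Prey
gradients below 1e-8 F_0 m⁻¹ (and flow/vorticity-gradient magnitudes below
1e-8 in native units) make the corresponding direction angle degenerate;
the affected coupling terms are dropped for that step.

## Integrator

Agents advance with the stochastic Heun (predictor-corrector) scheme; the
Wiener increment of L is drawn once per step and shared between stages, and
the state-dependent intensity D(A) is evaluated at the step's start (Itô
convention — at dt = 0.001–0.01 s the difference from Stratonovich is below
statistical resolution).  Angles are wrapped every step (θ to (−π, π], φ
mod 2π); positions are clamped 1e-6 m inside the walls as a safety net
beneath the wall force.  Coincident agents (pair distance < 1e-9 m) get a
capped repulsion of magnitude R_i/1e-9 with a seeded random push direction.
Reproducibility: a master seed spawns independent per-run (and per-twin)
generator streams via `numpy.random.SeedSequence`; a (seed, config) pair
yields bit-identical trajectories.

Initial conditions (the scenario "stated world"): positions uniform in the
whole tank for the cavity, in the right gyre (x > 0) for foraging, and —
a deliberate deviation — in the *downstream quarter* of the channel for
counter-current runs: the swarm's net upstream ground speed is
0.04–0.08 m s⁻¹, so a whole-channel release would pin a large fraction of
agents against the inlet wall within 300 s and contaminate the ensemble-mean
relative-velocity measurand, which the published translating-swarm
snapshots do not show.  θ and φ are uniform on the circle, A = 0, L is
drawn from its stationary normal distribution.

## Statistics

The indication number N(W) is the fraction of agents with W above the
passive twin's ensemble mean (ties count as not exceeding — fixed for
determinism).  The turbulence fraction P(|C|) and crossing fraction P(x)
are ratios of active to passive indication numbers, flagged NaN when the
passive denominator vanishes.  P_min discards the first 50 s, then averages
only samples below 0.9·min + 0.1·max (isolated spikes excluded).
Corr_V,U is the mean of the componentwise Pearson correlations between
agent velocities and sampled flow.  Hex_n is the ensemble mean of
|mean_k exp(i6δ_jk)| over each agent's n exact nearest neighbours
(KD-tree, index tie-break; n = 6 for wall effects, 12 to resolve
filamentation) — boundary agents use their n nearest regardless of wall
proximity, with no boundary correction.  The spread is
Σ = σ_x²(t)/2σ_x²(0) + σ_y²(t)/2σ_y²(0); the left-gyre variant Σ_0
restricts the numerator to agents at x < 0 and keeps the full initial
ensemble as reference.  K-run "double averages" smooth each run with a
Gaussian kernel — the 15 s window is interpreted as 4σ (σ = 3.75 s),
truncated at ±2σ and renormalised — then average across runs.

The counter-current measurand subtracts the local flow per agent *before*
ensemble averaging (time average of |mean_j(ẋ_j − U_j)| over the central
two-thirds of the run, divided by 0.067 m s⁻¹); this reading makes the
0.087 → 0.067 calibration self-consistent.

## Scaled-down defaults

Scans and tests default to frozen-flow replay at dt_agent = 0.005 s with
K = 4 repetitions instead of live CFD at dt = 0.001 s with K = 16 — a
speed/accuracy trade-off that is exact for steady flows and keeps the
suite inside commodity-hardware budgets.  The ε_F,0 scan grid is
log-spaced over [0.04, 0.64] rad s⁻¹ (the explored range; the printed grid
is not fully specified).  Directional assertions (e.g. P_min falls with
ε_C,0; mechanism subset A alone yields no barrier crossing) are tested on
smaller, shorter ensembles than the full experiments and establish
direction, not magnitude.

## Out of scope

Bell-phase coupling between agents and the attractive interaction branch
exist only as default-off toggles; anisotropic sensing/communication,
hydrodynamic (vortex-ring) agent coupling, agent inertia, two-way
fluid-agent coupling, turbulence modelling, 3D dynamics and first-passage
analyses are not implemented.
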