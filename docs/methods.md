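# Model and methods

## The model

`attnflock` simulates `N` self-propelled agents moving at constant speed
`v0` on an `L x L` torus that also contains `N_DS` fixed point-like danger
sites (DS), each surrounded by a disc-shaped repulsion zone of radius `r`.
The central ingredient is a hard attention limit: each agent can attend to
only its `k` nearest objects (kNO), where *objects* means other agents and
danger sites alike — social and environmental cues compete for the same
attention slots.

The heading angle `phi_i` of agent `i` obeys the stochastic equation

    dphi_i/dt = (1 - g_i) [ (gamma_s / n_s) sum_{j in kNO} sin(phi_j - phi_i)
                            - gamma_p sin(phi_i - psi_p) ]
                + g_i (gamma_l / n_l) sum_{l active} sin(alpha_il - phi_i)
                + eta xi_i(t)

with positions advanced as `dx_i/dt = v0 (cos phi_i, sin phi_i)`. The switch
`g_i = 1` iff at least one DS is simultaneously (a) inside the agent's kNO
set and (b) closer than `r`; such "active" sites dominate all other
behavior — a responding agent ignores its neighbors entirely. `alpha_il` is
the polar angle of the minimum-image displacement pointing from site `l` to
agent `i`, so the repulsion term rotates the heading toward the outward
direction. A DS inside the kNO but outside its repulsion zone is perceived
but ignored: it consumes an attention slot without exerting force (this is
what produces the emergent self-isolation at low `k`). The repulsion sum and
its normalizer `n_l` run only over active in-kNO sites; the alignment sum
and `n_s` run over the agent entries of the kNO set. Empty sums contribute
zero (an isolated agent moves ballistically plus noise).

A fixed fraction `R_inf` of agents is *informed*: only they feel the bias
`gamma_p` toward the preferred direction `u_p` (the +x axis by default,
`psi_p` its polar angle); `gamma_p = 0` for everyone else.

### Default parameters

| parameter | meaning | default | units |
|---|---|---|---|
| `v0` | speed | 0.5 | length/time |
| `gamma_s` | alignment strength | 1 | 1/time |
| `gamma_p` | informed bias strength | 0.1 | 1/time |
| `gamma_l` | DS repulsion strength | 1 | 1/time |
| `eta` | angular noise strength | 0.25 | rad/sqrt(time) |
| `r` | repulsion-zone radius | 1 | length |
| `L` | box size | 25 | length |
| `N` | agents (density 1) | 625 | — |
| `k` | attention capacity | per experiment | slots |
| `dt` | integration step | 0.1 | time |

These are the standard study conditions for all benchmark experiments;
`rho_DS = N_DS / L^2` and `R_inf` are the main control parameters besides
`k`.

## Numerical integration

Euler–Maruyama with step `dt = 0.1`: the angular update is
`phi += rate * dt + eta * sqrt(dt) * N(0,1)` (so the heading variance of a
free agent grows exactly as `eta^2 t`, which the test suite verifies within
5%). The update is synchronous — all turning rates are evaluated on the
pre-step configuration — and positions are then advanced with the
post-update headings, a standard choice for Vicsek-type models. Headings are
wrapped to `[-pi, pi)` and positions to `[0, L)` every step. Speed is
conserved exactly by construction.

Neighbor queries use a periodic KD-tree over the concatenated set of agents
and danger sites; the per-agent reference implementation
(`select_k_nearest_objects`) breaks exact distance ties by object index
(agents before sites) for determinism, a measure-zero concern for
continuous positions. All randomness in a run — initial condition, angular
noise, direct-detection draws — flows from a single seeded generator, so
matched seeds give bit-identical trajectories.

## Observables

* accuracy `C = < (1/N) sum_j u_j . u_p >`, averaged over stationary frames;
* polarization `C~ = < | (1/N) sum_j u_j | >`, the consensus order parameter
  used when no informed direction exists (always `C <= C~`);
* raw avoidance `A~ = 1 - <N_rz / N>` with `N_rz` the number of agents
  inside at least one repulsion zone, and the avoidance ratio
  `A = A~ / A~_ni` against a non-interacting control (below);
* fitness `F = C + beta (A - 1)`; `F = 0` is the solitary-agent reference;
* network statistics on the directed graph "i attends to j": degree
  distributions, connected components of the undirected projection,
  edge lifetimes (maximal contiguous presence-runs at the recording
  interval; runs truncated at the observation window's edges are included
  at their observed length by default, with a switch to drop them — the
  censoring convention is a free choice and is documented rather than
  hidden);
* responder fractions: `r_d` = fraction of agents with `g=1`; `r_i` =
  fraction of agents with `g=0` attending to at least one direct responder.
  `r_i` is computed among non-responders because responders have no social
  out-edges by construction; the per-frame fraction is averaged over frames
  (averaging before or after the ratio is a convention; we average the
  per-frame fractions).

## Non-interacting control

The control population for the avoidance ratio consists of solitary agents:
`gamma_s = 0`, and an agent inside a repulsion zone always responds to all
zones containing it (detection is not gated by the attention limit).
Internally this is expressed as `gamma_s=0, p_direct=1`, which makes the
attention capacity irrelevant to the control's dynamics; it is pinned to
`k=1` to keep neighbor queries cheap. Informed control agents keep their
`gamma_p` bias. The control shares the environment realization with its
paired main run but not the initial agent placement (the agents are
independent random walkers; their initial positions decorrelate within a
few time units).

## Model variants

* **Voronoi-restricted kNO** (`attention_mode="voronoi"`): social candidates
  are limited to the first Voronoi shell of the agent-only tessellation
  (computed periodically via 3x3 tiling), extended by the second shell when
  the first holds fewer than `k` members; danger sites are treated as in the
  base model. Degenerate tessellations fall back to the base rule with a
  warning.
* **Direct detection** (`p_direct`): an agent inside a zone detects all
  containing zones with probability `p_direct` per time step regardless of
  its attention slots. `p_direct=0` recovers the base model exactly (same
  trajectories under matched seeds); `p_direct=1` is perfect detection. The
  probability is interpreted per integration step, as its time
  discretization is a modeling choice.
* **Active signaling** (`signaling=True`): every non-responder whose slots
  contain at least one responding agent redirects its full social attention
  to exactly those signalers.

## Environments

Random environments place `N_DS` sites i.i.d. uniform (zones may overlap);
structured environments draw sites at a nominal density and then reject
those falling in a circular annulus (the "safe path"), leaving the annulus
exactly DS-free and the realized global density slightly below nominal.
The path geometry defaults to radius `L/3`, width 3, centered in the box —
exposed as parameters since only the qualitative geometry matters.

## Study sizes and stationarity

Benchmark presets use the full geometry (`N=625`, `L=25`, `dt=0.1`)
but a scaled-down averaging protocol chosen for single-CPU runs: 600 time
units per run with the first half discarded as transient and ~40 recorded
stationary frames, and 2–6 replicates per configuration. Development
diagnostics (windowed means of `C(t)`) show the danger-site configurations
plateau well before t=300. Two exceptions get longer windows: the
homogeneous-environment runs at 10% informed agents, where the onset of
global order from random initial conditions is slower (1200 time units,
600 burn-in), and the minimal-attention, few-informed configuration
(`k=1`, `N_inf=8`), whose consensus direction relaxes toward `u_p` on a
timescale of thousands of time units — directional information spreads only
through slow fission–fusion of small clusters, and runs may transiently
lock into a wrong-direction consensus (8000 time units, 4000 burn-in). Initial
conditions are always uniform-random positions and headings; informed
agents are drawn uniformly without replacement, `round(R_inf * N)` of them
(half-to-even rounding).

## What the tests do and do not show

The test suite verifies the implementation against closed forms (angular
diffusion, the random-heading polarization floor `sqrt(pi)/(2 sqrt(N))`),
independent brute-force oracles (exhaustive distance sorting, flood-fill
components, explicit Voronoi-shell construction), exact symmetries
(rotation by pi/2, torus translation), and the headline collective
phenomena at the study conditions: the accuracy-vs-k reversal between
homogeneous and DS-dense environments, responder-fraction saturation, and
the avoidance crossover `A(k) > 1` only at high `k`. These are statements
about the model, not about real animal groups: agents are point-like, speed
is fixed, interactions are noiseless and instantaneous, and "attention" is
a hard slot limit with purely distance-based salience.

## Known limitations

* The Voronoi variant is an order of magnitude slower than the KD-tree path
  (per-agent shell construction each step) and is intended for small-scale
  variant studies.
* Stationary averages at `k=1` with very few informed agents retain large
  seed-to-seed variability even after long burn-in; replicate counts matter
  more than window length there.
* Edge lifetimes are measured at the recording interval, not per step, so
  lifetimes shorter than the interval are censored.
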