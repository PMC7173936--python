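"""Stochastic equations of motion for attention-limited flocking.

Agents are self-propelled particles at constant speed ``v0`` on a periodic
box. The heading of agent ``i`` evolves as

    dphi_i/dt = (1 - g_i) [ (gamma_s / n_s) sum_{j in kNO} sin(phi_j - phi_i)
                            - gamma_p sin(phi_i - psi_p) ]
                + g_i (gamma_l / n_l) sum_{l active} sin(alpha_il - phi_i)
                + eta xi_i(t)

where ``g_i`` switches between social alignment (plus, for informed agents, a
bias of strength ``gamma_p`` toward the preferred direction ``u_p``) and
repulsion from the danger sites that are both inside the agent's attention
slots and inside their repulsion zone. ``alpha_il`` is the polar angle of the
minimum-image displacement from DS ``l`` to agent ``i``, so the repulsion term
turns the agent away from the site. ``xi`` is Gaussian white noise of unit
standard deviation; integration is Euler–Maruyama with angular increment
``eta * sqrt(dt) * N(0, 1)``. All agents are updated synchronously from the
pre-step configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .attention import AttentionMatrix, AttentionSet, attention_matrix, voronoi_restricted_kno, voronoi_shells
from .environment import EnvironmentSpec, minimum_image_displacement

__all__ = [
    "ModelParams",
    "AgentState",
    "FrameRecord",
    "SimulationResult",
    "deterministic_turning_rate",
    "step",
    "initialize_state",
    "run_simulation",
]


@dataclass(frozen=True)
class ModelParams:
    """Model parameters (defaults are the standard study values).

    ``gamma_p`` applies only to informed agents; ``k`` is the attention
    capacity (number of attention slots). Variant switches: ``attention_mode``
    ("knn" or "voronoi"), ``p_direct`` (probabilistic direct DS detection,
    0 recovers the base model, 1 is perfect detection) and ``signaling``
    (direct responders broadcast and monopolize their neighbors' attention).
    """

    v0: float = 0.5
    gamma_s: float = 1.0
    gamma_p: float = 0.1
    gamma_l: float = 1.0
    eta: float = 0.25
    k: int = 6
    dt: float = 0.1
    u_p: tuple[float, float] = (1.0, 0.0)
    attention_mode: str = "knn"
    p_direct: float = 0.0
    signaling: bool = False

    def __post_init__(self) -> None:
        if self.v0 <= 0:
            raise ValueError(f"v0 must be positive, got {self.v0}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.eta < 0:
            raise ValueError(f"eta must be non-negative, got {self.eta}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if not 0.0 <= self.p_direct <= 1.0:
            raise ValueError(f"p_direct must be in [0, 1], got {self.p_direct}")
        if self.attention_mode not in ("knn", "voronoi"):
            raise ValueError(f"unknown attention_mode {self.attention_mode!r}")
        norm = math.hypot(*self.u_p)
        if not math.isclose(norm, 1.0, rel_tol=1e-9):
            if norm == 0:
                raise ValueError("u_p must be a non-zero direction")
            object.__setattr__(self, "u_p", (self.u_p[0] / norm, self.u_p[1] / norm))

    @property
    def preferred_angle(self) -> float:
        return math.atan2(self.u_p[1], self.u_p[0])


@dataclass
class AgentState:
    """Positions, headings and informed flags of all agents.

    ``g`` holds the danger-response flags of the most recent step (None before
    the first step). Positions are kept wrapped into ``[0, L)``; headings into
    ``[-pi, pi)``.
    """

    positions: np.ndarray
    headings: np.ndarray
    informed: np.ndarray
    g: np.ndarray | None = None

    @property
    def n_agents(self) -> int:
        return len(self.positions)

    def copy(self) -> "AgentState":
        return AgentState(
            self.positions.copy(),
            self.headings.copy(),
            self.informed.copy(),
            None if self.g is None else self.g.copy(),
        )


@dataclass
class FrameRecord:
    """One recorded frame: configuration plus the attention state used for it.

    ``att`` is the attention matrix of the frame; ``social_mask`` marks the
    slots that count as social out-edges (post-signaling, if enabled) — note
    that agents with ``g=1`` ignore these socially regardless.
    """

    time: float
    positions: np.ndarray
    headings: np.ndarray
    g: np.ndarray
    att: AttentionMatrix
    social_mask: np.ndarray


@dataclass
class SimulationResult:
    env: EnvironmentSpec
    params: ModelParams
    seed: int | None
    informed: np.ndarray
    frames: list[FrameRecord]
    final_state: AgentState
    record_spacing: float = 0.0  # time units between recorded frames

    @property
    def n_agents(self) -> int:
        return len(self.informed)

    def headings_per_frame(self) -> np.ndarray:
        return np.array([f.headings for f in self.frames])

    def positions_per_frame(self) -> np.ndarray:
        return np.array([f.positions for f in self.frames])


def _wrap_angle(phi: np.ndarray) -> np.ndarray:
    return (phi + np.pi) % (2.0 * np.pi) - np.pi


def initialize_state(
    n_agents: int, r_inf: float, box_size: float, seed: int | None = None
) -> AgentState:
    """Uniform random initial condition with ``round(r_inf * N)`` informed agents.

    Rounding is Python's round-half-to-even, so e.g. N=625, r_inf=0.1 gives
    exactly 62 informed agents. Informed agents are chosen uniformly without
    replacement; flags are fixed for the run.
    """
    if not 0.0 <= r_inf <= 1.0:
        raise ValueError(f"r_inf must be in [0, 1], got {r_inf}")
    rng = np.random.default_rng(seed)
    positions = rng.uniform(0.0, box_size, size=(n_agents, 2))
    headings = rng.uniform(-np.pi, np.pi, size=n_agents)
    n_inf = round(r_inf * n_agents)
    informed = np.zeros(n_agents, dtype=bool)
    informed[rng.choice(n_agents, size=n_inf, replace=False)] = True
    return AgentState(positions, headings, informed)


def deterministic_turning_rate(
    focal: int,
    att: AttentionSet,
    state: AgentState,
    params: ModelParams,
    env: EnvironmentSpec | None = None,
) -> float:
    """Deterministic part of dphi/dt for one agent, from its attention set.

    Scalar reference implementation of the turning response; the simulation
    loop uses the vectorized equivalent. A responding agent (``g=1``) turns
    away from its active sites only; a non-responder aligns with its social
    entries and, if informed, biases toward the preferred direction. Empty
    sums contribute zero. ``env`` is required only when the agent has active
    DS entries (the repulsion angle needs the site positions).
    """
    phi_i = float(state.headings[focal])
    active = att.active_ds_ids()
    if active:
        if env is None:
            raise ValueError("env required to evaluate DS repulsion")
        disp = minimum_image_displacement(
            env.ds_positions[active], state.positions[focal], env.box_size
        )
        alpha = np.arctan2(disp[:, 1], disp[:, 0])
        return params.gamma_l / len(active) * float(np.sum(np.sin(alpha - phi_i)))
    social = att.social_ids()
    rate = 0.0
    if social:
        rate += params.gamma_s / len(social) * float(
            np.sum(np.sin(state.headings[social] - phi_i))
        )
    if state.informed[focal]:
        rate -= params.gamma_p * math.sin(phi_i - params.preferred_angle)
    return rate


class _Stepper:
    """Per-run integrator caching the DS KD-tree and static arrays."""

    def __init__(self, env: EnvironmentSpec, params: ModelParams):
        self.env = env
        self.params = params
        self.ds_tree = (
            cKDTree(env.ds_positions, boxsize=env.box_size) if env.n_ds else None
        )

    def _attention(self, positions: np.ndarray) -> AttentionMatrix:
        if self.params.attention_mode == "voronoi":
            return self._voronoi_attention(positions)
        return attention_matrix(positions, self.env, self.params.k)

    def _voronoi_attention(self, positions: np.ndarray) -> AttentionMatrix:
        n, k = len(positions), self.params.k
        shells = voronoi_shells(positions, self.env.box_size)
        idx = np.full((n, k), -1, dtype=np.int64)
        dist = np.full((n, k), np.inf)
        state = AgentState(positions, np.zeros(n), np.zeros(n, dtype=bool))
        for i in range(n):
            att = voronoi_restricted_kno(i, state, self.env, k, shells=shells)
            for s, e in enumerate(att.entries):
                idx[i, s] = e.object_id if e.kind == "agent" else n + e.object_id
                dist[i, s] = e.distance
        return AttentionMatrix(idx, dist, n)

    def turning_terms(
        self, state: AgentState, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray, AttentionMatrix, np.ndarray]:
        """Deterministic turning rates, g flags, attention and social mask."""
        env, p = self.env, self.params
        pos, phi = state.positions, state.headings
        n = len(pos)
        att = self._attention(pos)
        r = env.repulsion_radius

        active = att.active_ds(r)  # (n, k): in-slot DS inside its zone
        g = active.any(axis=1)

        # repulsion sums over active in-slot sites
        rep_sum = np.zeros(n)
        n_l = active.sum(axis=1)
        rows, cols = np.nonzero(active)
        if len(rows):
            ds_xy = env.ds_positions[att.idx[rows, cols] - n]
            disp = minimum_image_displacement(ds_xy, pos[rows], env.box_size)
            alpha = np.arctan2(disp[:, 1], disp[:, 0])
            np.add.at(rep_sum, rows, np.sin(alpha - phi[rows]))

        # probabilistic direct detection: agents inside >=1 zone respond to
        # all containing zones with probability p_direct per step
        if p.p_direct > 0.0 and self.ds_tree is not None:
            agent_tree = cKDTree(pos, boxsize=env.box_size)
            pairs = agent_tree.sparse_distance_matrix(
                self.ds_tree, max_distance=r * (1 - 1e-12), output_type="coo_matrix"
            )
            inside = np.zeros(n, dtype=bool)
            inside[pairs.row] = True
            override = inside & (rng.random(n) < p.p_direct)
            if override.any():
                g = g | override
                # recompute repulsion over *all* containing zones for overrides
                sel = override[pairs.row]
                o_rows = pairs.row[sel]
                ds_xy = env.ds_positions[pairs.col[sel]]
                disp = minimum_image_displacement(ds_xy, pos[o_rows], env.box_size)
                alpha = np.arctan2(disp[:, 1], disp[:, 0])
                rep_sum[override] = 0.0
                n_l_all = np.zeros(n, dtype=int)
                np.add.at(rep_sum, o_rows, np.sin(alpha - phi[o_rows]))
                np.add.at(n_l_all, o_rows, 1)
                n_l = np.where(override, n_l_all, n_l)

        # social alignment (only matters where g=0)
        social = att.is_agent
        if p.signaling:
            tgt = np.where(social, att.idx, 0)
            signaler = social & g[tgt]
            has_signaler = signaler.any(axis=1) & ~g
            social = np.where(has_signaler[:, None], signaler, social)
        n_s = social.sum(axis=1)
        tgt_phi = np.where(social, phi[np.where(social, att.idx, 0)], 0.0)
        align_sum = np.where(social, np.sin(tgt_phi - phi[:, None]), 0.0).sum(axis=1)

        with np.errstate(invalid="ignore", divide="ignore"):
            align = np.where(n_s > 0, p.gamma_s * align_sum / np.maximum(n_s, 1), 0.0)
            rep = np.where(n_l > 0, p.gamma_l * rep_sum / np.maximum(n_l, 1), 0.0)
        bias = p.gamma_p * np.sin(phi - p.preferred_angle) * state.informed
        gi = g.astype(float)
        rate = (1.0 - gi) * (align - bias) + gi * rep
        return rate, g, att, social

    def integrate(
        self,
        state: AgentState,
        rate: np.ndarray,
        g: np.ndarray,
        rng: np.random.Generator,
    ) -> AgentState:
        """Apply heading increment and advance positions (synchronous update)."""
        p, env = self.params, self.env
        noise = p.eta * math.sqrt(p.dt) * rng.standard_normal(state.n_agents)
        phi = _wrap_angle(state.headings + rate * p.dt + noise)
        vel = p.v0 * np.column_stack([np.cos(phi), np.sin(phi)])
        pos = (state.positions + vel * p.dt) % env.box_size
        if not np.isfinite(phi).all() or not np.isfinite(pos).all():
            bad = int(
                np.nonzero(~(np.isfinite(phi) & np.isfinite(pos).all(axis=1)))[0][0]
            )
            raise FloatingPointError(f"non-finite state for agent {bad}")
        return AgentState(pos, phi, state.informed, g)

    def advance(self, state: AgentState, rng: np.random.Generator) -> AgentState:
        rate, g, _, _ = self.turning_terms(state, rng)
        return self.integrate(state, rate, g, rng)


def step(
    state: AgentState,
    env: EnvironmentSpec,
    params: ModelParams,
    rng: np.random.Generator,
) -> AgentState:
    """One synchronous Euler–Maruyama step (all rates from the pre-step state)."""
    return _Stepper(env, params).advance(state, rng)


def run_simulation(
    env: EnvironmentSpec,
    params: ModelParams,
    n_agents: int | None = None,
    r_inf: float = 0.1,
    total_time: float = 600.0,
    burn_in_time: float | None = None,
    record_every: int | None = None,
    seed: int | None = None,
    initial_state: AgentState | None = None,
    progress=None,
) -> SimulationResult:
    """Integrate the model and record stationary frames.

    Parameters
    ----------
    n_agents:
        Number of agents; defaults to density 1 (``N = L**2``).
    r_inf:
        Informed fraction (ignored if ``initial_state`` is given).
    total_time, burn_in_time:
        Simulated time span; frames before ``burn_in_time`` (default: half of
        ``total_time``) are discarded as transient.
    record_every:
        Recording interval in steps (default: every 10 time units).
    progress:
        Optional callable ``progress(step, n_steps)`` invoked every 1000 steps.

    All randomness (initial condition, angular noise, direct-detection draws)
    flows from one generator seeded with ``seed``, so matched seeds give
    bit-identical trajectories.
    """
    if total_time <= 0:
        raise ValueError(f"total_time must be positive, got {total_time}")
    if burn_in_time is None:
        burn_in_time = total_time / 2.0
    if not 0.0 <= burn_in_time < total_time:
        raise ValueError(
            f"need 0 <= burn_in_time < total_time, got {burn_in_time} vs {total_time}"
        )
    if record_every is None:
        record_every = max(1, round(10.0 / params.dt))
    if record_every < 1:
        raise ValueError(f"record_every must be >= 1, got {record_every}")

    rng = np.random.default_rng(seed)
    if initial_state is None:
        if n_agents is None:
            n_agents = int(round(env.box_size**2))
        init_seed = int(rng.integers(0, 2**31 - 1))
        state = initialize_state(n_agents, r_inf, env.box_size, seed=init_seed)
    else:
        state = initial_state.copy()

    stepper = _Stepper(env, params)
    n_steps = int(round(total_time / params.dt))
    burn_steps = int(round(burn_in_time / params.dt))
    frames: list[FrameRecord] = []
    for s in range(n_steps):
        if progress is not None and s % 1000 == 0:
            progress(s, n_steps)
        record = s >= burn_steps and (s - burn_steps) % record_every == 0
        if record:
            rate, g, att, social = stepper.turning_terms(state, rng)
            frames.append(
                FrameRecord(
                    time=s * params.dt,
                    positions=state.positions.copy(),
                    headings=state.headings.copy(),
                    g=g.copy(),
                    att=att,
                    social_mask=social.copy(),
                )
            )
            state = stepper.integrate(state, rate, g, rng)
        else:
            state = stepper.advance(state, rng)
    return SimulationResult(
        env=env,
        params=params,
        seed=seed,
        informed=state.informed.copy(),
        frames=frames,
        record_spacing=record_every * params.dt,
        final_state=state,
    )
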