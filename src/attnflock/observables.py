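"""Order parameters, avoidance/fitness measures and interaction-network statistics.

Scalar observables
------------------
* accuracy ``C``: time-averaged mean projection of unit headings on the
  preferred direction ``u_p`` — 1 for perfect migration, ~0 for disorder.
* polarization ``C~``: time-averaged magnitude of the mean heading vector —
  the consensus order parameter, meaningful also without informed agents.
* raw avoidance ``A~ = 1 - <N_rz/N>``: fraction of agents outside every
  repulsion zone, and its ratio ``A = A~ / A~_ni`` against a non-interacting
  control (``A > 1``: social interactions help avoidance).
* fitness ``F = C + beta (A - 1)``: accuracy/avoidance trade-off; ``F = 0`` is
  the solitary-individual reference (C=0, A=1).

Network statistics are computed on the emergent directed attention network:
edge ``i -> j`` means agent ``j`` is in ``i``'s social out-neighborhood and
``i`` is not currently responding to a danger site (responders have out-degree
zero by construction, though others may still attend to them).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .attention import AttentionSet
from .dynamics import FrameRecord, SimulationResult
from .environment import EnvironmentSpec

__all__ = [
    "RunSummary",
    "accuracy",
    "polarization",
    "raw_avoidance",
    "avoidance_ratio",
    "fitness",
    "build_interaction_network",
    "frame_network",
    "connected_components",
    "responder_fractions",
    "edge_lifetime",
    "degree_distribution",
    "summarize_run",
]


@dataclass
class RunSummary:
    """Time-averaged observables of one stationary run."""

    C: float
    C_tilde: float
    A_tilde: float
    r_d: float
    r_i: float
    n_components_mean: float
    mean_edge_lifetime: float | None = None
    A: float | None = None
    F: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _as_frames(headings) -> np.ndarray:
    arr = np.asarray(headings, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.size == 0:
        raise ValueError("need at least one recorded frame")
    return arr


def accuracy(headings_per_frame, u_p=(1.0, 0.0)) -> float:
    """Collective accuracy C: mean projection of headings on ``u_p``."""
    phi = _as_frames(headings_per_frame)
    psi = np.arctan2(u_p[1], u_p[0])
    return float(np.mean(np.cos(phi - psi)))


def polarization(headings_per_frame) -> float:
    """Polarization C~: time average of the mean-heading-vector magnitude."""
    phi = _as_frames(headings_per_frame)
    mean_u = np.stack(
        [np.cos(phi).mean(axis=1), np.sin(phi).mean(axis=1)], axis=-1
    )
    return float(np.mean(np.linalg.norm(mean_u, axis=-1)))


def raw_avoidance(positions_per_frame, env: EnvironmentSpec) -> float:
    """Raw avoidance A~ = 1 - <N_rz/N> (torus metric).

    ``N_rz`` counts agents inside at least one repulsion disc.
    """
    pos = np.asarray(positions_per_frame, dtype=float)
    if pos.ndim == 2:
        pos = pos[None, :, :]
    if pos.size == 0:
        raise ValueError("need at least one recorded frame")
    if env.n_ds == 0:
        return 1.0
    tree = cKDTree(env.ds_positions, boxsize=env.box_size)
    frac_inside = [
        np.mean(tree.query(frame)[0] < env.repulsion_radius) for frame in pos
    ]
    return float(1.0 - np.mean(frac_inside))


def avoidance_ratio(a_tilde_main: float, a_tilde_control: float) -> float:
    """Avoidance ratio A = A~ / A~_ni; A=1 means parity with solitary agents."""
    if a_tilde_control == 0:
        raise ZeroDivisionError(
            "control raw avoidance is 0; avoidance ratio undefined"
        )
    return a_tilde_main / a_tilde_control


def fitness(C: float, A: float, beta: float) -> float:
    """Global fitness F = C + beta (A - 1); F=0 is the solitary reference."""
    return C + beta * (A - 1.0)


# ---------------------------------------------------------------------------
# Interaction networks
# ---------------------------------------------------------------------------


def build_interaction_network(
    attention_sets: list[AttentionSet],
    g_flags,
    informed=None,
) -> nx.DiGraph:
    """Directed social attention network of one frame.

    Edge ``i -> j`` for every agent ``j`` among ``i``'s social entries, but
    only when ``g_i = 0`` — direct responders ignore their neighbors, so their
    out-degree is zero (their in-degree may not be).
    """
    g = np.asarray(g_flags).astype(bool)
    net = nx.DiGraph()
    for att in attention_sets:
        i = att.focal_id
        net.add_node(
            i,
            g=int(g[i]),
            informed=bool(informed[i]) if informed is not None else None,
        )
        if g[i]:
            continue
        for j in att.social_ids():
            net.add_edge(i, j)
    # targets that never appear as focal still need attributes
    for j in net.nodes:
        if "g" not in net.nodes[j]:
            net.nodes[j]["g"] = int(g[j])
            net.nodes[j]["informed"] = (
                bool(informed[j]) if informed is not None else None
            )
    return net


def frame_network(frame: FrameRecord, informed=None) -> nx.DiGraph:
    """Directed social network from a recorded simulation frame."""
    net = nx.DiGraph()
    net.add_nodes_from(
        (
            i,
            {
                "g": int(frame.g[i]),
                "informed": bool(informed[i]) if informed is not None else None,
            },
        )
        for i in range(len(frame.g))
    )
    rows, cols = np.nonzero(frame.social_mask & ~frame.g[:, None])
    net.add_edges_from(zip(rows.tolist(), frame.att.idx[rows, cols].tolist()))
    return net


def connected_components(network: nx.Graph) -> tuple[int, list[int]]:
    """Component count and sizes of the undirected projection."""
    und = network.to_undirected() if network.is_directed() else network
    sizes = sorted((len(c) for c in nx.connected_components(und)), reverse=True)
    return len(sizes), sizes


def responder_fractions(network: nx.DiGraph, g_flags) -> tuple[float, float]:
    """Direct (r_d) and first-order indirect (r_i) responder fractions.

    ``r_d`` is the fraction of agents with ``g=1``; ``r_i`` the fraction of
    agents with ``g=0`` that have at least one out-edge to a direct responder.
    Both are fractions of the whole group.
    """
    g = np.asarray(g_flags).astype(bool)
    n = len(g)
    r_d = float(g.mean()) if n else 0.0
    indirect = sum(
        1
        for i in network.nodes
        if not g[i] and any(g[j] for j in network.successors(i))
    )
    return r_d, indirect / n if n else 0.0


def _frame_responders(frame: FrameRecord) -> tuple[float, float]:
    g = frame.g
    social = frame.social_mask & ~g[:, None]
    tgt_g = np.where(social, g[np.where(social, frame.att.idx, 0)], False)
    r_i = float((tgt_g.any(axis=1) & ~g).mean())
    return float(g.mean()), r_i


def edge_lifetime(
    edge_sets: list[set], frame_spacing: float = 1.0, include_censored: bool = True
) -> float:
    """Mean lifetime of undirected edges over equally spaced frames.

    A lifetime is the length of a maximal contiguous presence-run of an edge,
    in time units (run length x frame spacing). Runs truncated by the first or
    last frame are counted at their observed length unless
    ``include_censored=False``.
    """
    if len(edge_sets) < 2:
        raise ValueError("edge lifetimes need at least two frames")
    runs: list[tuple[int, bool]] = []  # (length, censored)
    active: dict = {}  # edge -> (run length so far, started at frame 0)
    for t, edges in enumerate(edge_sets):
        edges = {tuple(sorted(e)) for e in edges}
        for e in list(active):
            if e not in edges:
                length, from_start = active.pop(e)
                runs.append((length, from_start))
        for e in edges:
            if e in active:
                active[e] = (active[e][0] + 1, active[e][1])
            else:
                active[e] = (1, t == 0)
    runs.extend((length, True) for length, _ in active.values())  # right-censored
    if not include_censored:
        runs = [r for r in runs if not r[1]]
    if not runs:
        return float("nan")
    return float(np.mean([length for length, _ in runs]) * frame_spacing)


def degree_distribution(result: SimulationResult) -> pd.DataFrame:
    """Long-format (degree_in, degree_out, count) histogram pooled over frames."""
    counts: dict[tuple[int, int], int] = {}
    for frame in result.frames:
        net = frame_network(frame)
        for i in net.nodes:
            key = (net.in_degree(i), net.out_degree(i))
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {"degree_in": di, "degree_out": do, "count": c}
        for (di, do), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["degree_in", "degree_out", "count"])


def summarize_run(
    result: SimulationResult,
    a_tilde_control: float | None = None,
    beta: float | None = None,
    edge_lifetimes: bool = True,
) -> RunSummary:
    """All stationary time-averaged observables of one run."""
    if not result.frames:
        raise ValueError("run has no recorded frames")
    phi = result.headings_per_frame()
    pos = result.positions_per_frame()
    C = accuracy(phi, result.params.u_p)
    C_t = polarization(phi)
    A_tilde = raw_avoidance(pos, result.env)
    rd_ri = np.array([_frame_responders(f) for f in result.frames])
    nets = [frame_network(f) for f in result.frames]
    n_comp = float(np.mean([connected_components(net)[0] for net in nets]))
    lifetime = None
    if edge_lifetimes and len(nets) >= 2:
        edge_sets = [
            {tuple(sorted(e)) for e in net.edges} for net in nets
        ]
        lifetime = edge_lifetime(edge_sets, result.record_spacing)
    A = F = None
    if a_tilde_control is not None:
        A = avoidance_ratio(A_tilde, a_tilde_control)
        if beta is not None:
            F = fitness(C, A, beta)
    return RunSummary(
        C=C,
        C_tilde=C_t,
        A_tilde=A_tilde,
        r_d=float(rd_ri[:, 0].mean()),
        r_i=float(rd_ri[:, 1].mean()),
        n_components_mean=n_comp,
        mean_edge_lifetime=lifetime,
        A=A,
        F=F,
    )
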