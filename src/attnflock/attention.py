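"""k-nearest-object (kNO) attention.

Each agent has ``k`` attention slots and fills them with the ``k`` nearest
objects around it — other agents (social cues) and danger sites (non-social
cues) compete for the same slots. An agent responds to a danger site (``g=1``)
only if the site occupies one of its slots *and* lies inside its repulsion
zone (distance < ``r``); a perceived site outside the zone still consumes a
slot but is ignored. Variants: Voronoi-shell-restricted candidate sets,
probabilistic direct detection of containing zones, and active signaling by
direct responders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from .environment import EnvironmentSpec, minimum_image_displacement, torus_distance

__all__ = [
    "AttendedObject",
    "AttentionSet",
    "AttentionMatrix",
    "select_k_nearest_objects",
    "attention_matrix",
    "evaluate_danger_response",
    "voronoi_restricted_kno",
    "voronoi_shells",
    "apply_direct_detection",
    "apply_signaling",
]


class AttendedObject(NamedTuple):
    object_id: int  # agent index or DS index (within its kind)
    kind: str  # "agent" | "ds"
    distance: float


@dataclass
class AttentionSet:
    """Ordered attention slots of one focal agent.

    ``entries`` are sorted by distance ascending; ties are broken by global
    object index (agents before danger sites, lower index first) so results
    are deterministic.
    """

    focal_id: int
    entries: list[AttendedObject]
    repulsion_radius: float

    @property
    def n_s(self) -> int:
        """Number of social (agent) entries."""
        return sum(1 for e in self.entries if e.kind == "agent")

    @property
    def n_l_active(self) -> int:
        """Number of DS entries inside the repulsion zone (distance < r)."""
        return sum(
            1
            for e in self.entries
            if e.kind == "ds" and e.distance < self.repulsion_radius
        )

    @property
    def g(self) -> int:
        """Danger-response flag: 1 iff at least one in-slot DS is within r."""
        return int(self.n_l_active >= 1)

    def social_ids(self) -> list[int]:
        return [e.object_id for e in self.entries if e.kind == "agent"]

    def active_ds_ids(self) -> list[int]:
        return [
            e.object_id
            for e in self.entries
            if e.kind == "ds" and e.distance < self.repulsion_radius
        ]


def _positions_of(state) -> np.ndarray:
    # accept an AgentState or a bare (N, 2) array
    return np.asarray(getattr(state, "positions", state), dtype=float)


def select_k_nearest_objects(
    focal: int, state, env: EnvironmentSpec, k: int
) -> AttentionSet:
    """Fill the focal agent's ``k`` slots with its globally nearest objects.

    Candidates are all other agents plus all danger sites; distances use the
    torus metric. DS entries occupy slots regardless of whether they lie
    inside the repulsion zone.
    """
    if k < 1:
        raise ValueError(f"attention limit k must be >= 1, got {k}")
    pos = _positions_of(state)
    n = len(pos)
    all_points = np.vstack([pos, env.ds_positions]) if env.n_ds else pos
    d = torus_distance(all_points, pos[focal], env.box_size)
    d[focal] = np.inf  # exclude self
    order = np.lexsort((np.arange(len(d)), d))  # distance, then global index
    order = order[: min(k, len(d) - 1)]
    entries = [
        AttendedObject(int(i) if i < n else int(i - n), "agent" if i < n else "ds", float(d[i]))
        for i in order
    ]
    return AttentionSet(focal, entries, env.repulsion_radius)


class AttentionMatrix(NamedTuple):
    """Vectorized attention sets for all agents at one instant.

    ``idx`` holds global object indices (``0..N-1`` agents, ``N..N+N_DS-1``
    danger sites, ``-1`` empty slot); ``dist`` the matching torus distances
    (``inf`` for empty slots). Shapes are ``(N, k)``.
    """

    idx: np.ndarray
    dist: np.ndarray
    n_agents: int

    @property
    def is_agent(self) -> np.ndarray:
        return (self.idx >= 0) & (self.idx < self.n_agents)

    @property
    def is_ds(self) -> np.ndarray:
        return self.idx >= self.n_agents

    def active_ds(self, repulsion_radius: float) -> np.ndarray:
        """Mask of DS entries inside the repulsion zone."""
        return self.is_ds & (self.dist < repulsion_radius)

    def g_flags(self, repulsion_radius: float) -> np.ndarray:
        return self.active_ds(repulsion_radius).any(axis=1)


def attention_matrix(
    positions: np.ndarray, env: EnvironmentSpec, k: int
) -> AttentionMatrix:
    """kNO selection for every agent at once via a periodic KD-tree.

    Equivalent to :func:`select_k_nearest_objects` row by row (up to ordering
    of exactly tied distances, a measure-zero event for continuous positions).
    """
    if k < 1:
        raise ValueError(f"attention limit k must be >= 1, got {k}")
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    points = np.vstack([pos, env.ds_positions]) if env.n_ds else pos
    m = len(points)
    tree = cKDTree(points, boxsize=env.box_size)
    kq = min(k + 1, m)  # +1: the focal agent itself is among the hits
    dist, idx = tree.query(pos, k=kq)
    if kq == 1:
        dist, idx = dist[:, None], idx[:, None]
    valid = idx < m
    not_self = idx != np.arange(n)[:, None]
    sel = valid & not_self
    keep = sel & (np.cumsum(sel, axis=1) <= k)

    out_idx = np.full((n, k), -1, dtype=np.int64)
    out_dist = np.full((n, k), np.inf)
    rows, cols = np.nonzero(keep)
    slot = np.cumsum(keep, axis=1)[rows, cols] - 1
    out_idx[rows, slot] = idx[rows, cols]
    out_dist[rows, slot] = dist[rows, cols]
    return AttentionMatrix(out_idx, out_dist, n)


def evaluate_danger_response(
    att: AttentionSet, r: float | None = None
) -> tuple[int, list[int]]:
    """Danger-response switch: ``g=1`` iff an in-slot DS lies within ``r``.

    Returns ``(g, active_ds_ids)`` — the DS indices the agent turns away from.
    """
    radius = att.repulsion_radius if r is None else r
    active = [
        e.object_id for e in att.entries if e.kind == "ds" and e.distance < radius
    ]
    return (1 if active else 0), active


# ---------------------------------------------------------------------------
# Voronoi-restricted variant
# ---------------------------------------------------------------------------


def voronoi_shells(positions: np.ndarray, box_size: float) -> list[set[int]]:
    """First Voronoi shell (Delaunay neighbors) of every agent on the torus.

    The periodic tessellation is obtained by tiling the box 3x3 and reading
    off adjacencies of the central copy.
    """
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    if n < 4:
        raise ValueError("Voronoi tessellation needs at least 4 agents")
    shifts = np.array(
        [[dx, dy] for dx in (-1, 0, 1) for dy in (-1, 0, 1)], dtype=float
    )
    tiled = (pos[None, :, :] + shifts[:, None, :] * box_size).reshape(-1, 2)
    tri = Delaunay(tiled)
    # central copy occupies rows [4n, 5n) given shift ordering (0,0) at index 4
    center0 = 4 * n
    adj: list[set[int]] = [set() for _ in range(n)]
    for simplex in tri.simplices:
        owners = simplex % n
        central = (simplex >= center0) & (simplex < center0 + n)
        if not central.any():
            continue
        for a in range(3):
            if not central[a]:
                continue
            i = owners[a]
            for b in range(3):
                if b != a and owners[b] != i:
                    adj[i].add(int(owners[b]))
    return adj


def voronoi_restricted_kno(
    focal: int, state, env: EnvironmentSpec, k: int, shells: list[set[int]] | None = None
) -> AttentionSet:
    """kNO with social candidates restricted to Voronoi shells.

    Agent candidates are the focal agent's first Voronoi shell, extended by the
    second shell (Voronoi neighbors of neighbors) when the first holds fewer
    than ``k`` members. Danger sites are treated exactly as in the base model
    (they are not part of the tessellation). Degenerate configurations fall
    back to the base kNO selection with a warning.
    """
    if k < 1:
        raise ValueError(f"attention limit k must be >= 1, got {k}")
    pos = _positions_of(state)
    n = len(pos)
    if shells is None:
        try:
            shells = voronoi_shells(pos, env.box_size)
        except (QhullError, ValueError) as err:
            warnings.warn(
                f"Voronoi tessellation failed ({err}); falling back to base kNO",
                RuntimeWarning,
                stacklevel=2,
            )
            return select_k_nearest_objects(focal, state, env, k)
    candidates = set(shells[focal])
    if len(candidates) < k:
        second = set().union(*(shells[j] for j in candidates)) if candidates else set()
        candidates |= second - {focal}
    cand = sorted(candidates)
    d_agents = torus_distance(pos[cand], pos[focal], env.box_size) if cand else np.empty(0)
    d_ds = (
        torus_distance(env.ds_positions, pos[focal], env.box_size)
        if env.n_ds
        else np.empty(0)
    )
    gids = np.concatenate([np.asarray(cand, dtype=int), n + np.arange(env.n_ds)])
    dists = np.concatenate([d_agents, d_ds])
    order = np.lexsort((gids, dists))[: min(k, len(gids))]
    entries = [
        AttendedObject(
            int(g) if g < n else int(g - n), "agent" if g < n else "ds", float(dd)
        )
        for g, dd in zip(gids[order], dists[order])
    ]
    return AttentionSet(focal, entries, env.repulsion_radius)


# ---------------------------------------------------------------------------
# Direct-detection and signaling variants
# ---------------------------------------------------------------------------


def apply_direct_detection(
    focal_position, env: EnvironmentSpec, p_direct: float, rng: np.random.Generator
) -> tuple[bool, np.ndarray]:
    """Probabilistic detection of containing zones, bypassing attention slots.

    If the focal agent sits inside at least one repulsion zone, it detects
    (and responds to) *all* containing zones with probability ``p_direct``
    per time step, independent of its social neighborhood. Returns
    ``(override, containing_ds_indices)``; ``override`` is always False
    outside every zone.
    """
    if not 0.0 <= p_direct <= 1.0:
        raise ValueError(f"p_direct must be in [0, 1], got {p_direct}")
    if env.n_ds == 0:
        return False, np.empty(0, dtype=int)
    d = torus_distance(env.ds_positions, np.asarray(focal_position, float), env.box_size)
    containing = np.nonzero(d < env.repulsion_radius)[0]
    if len(containing) == 0:
        return False, containing
    return bool(rng.random() < p_direct), containing


def apply_signaling(
    att_all: list[AttentionSet], g_all: np.ndarray
) -> list[AttentionSet]:
    """Active signaling by direct responders.

    Every non-responding agent whose slots contain at least one signaling
    (``g=1``) agent replaces its social entries by exactly those signalers,
    ignoring other social cues; DS entries and responders are unchanged.
    """
    g = np.asarray(g_all).astype(bool)
    out: list[AttentionSet] = []
    for att in att_all:
        if g[att.focal_id]:
            out.append(att)
            continue
        signalers = [
            e for e in att.entries if e.kind == "agent" and g[e.object_id]
        ]
        if not signalers:
            out.append(att)
            continue
        kept = [e for e in att.entries if e.kind == "ds"] + signalers
        kept.sort(key=lambda e: (e.distance, e.object_id))
        out.append(AttentionSet(att.focal_id, kept, att.repulsion_radius))
    return out
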