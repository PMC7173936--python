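"""Periodic 2-D arenas with fixed danger sites.

The arena is an ``L x L`` torus. Danger sites (DS) are fixed point cues, each
surrounded by a disc-shaped repulsion zone of radius ``r``; agents that detect
a DS inside its zone turn away from it. Environments are either fully random
(uniform DS field at areal density ``rho_DS = N_DS / L**2``) or structured
(random field with an exactly DS-free circular path).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EnvironmentSpec",
    "generate_random_environment",
    "generate_structured_environment",
    "minimum_image_displacement",
    "torus_distance",
]


@dataclass(frozen=True)
class EnvironmentSpec:
    """Immutable arena description: box size, DS positions, repulsion radius.

    Attributes
    ----------
    box_size:
        Linear size ``L`` of the periodic box; coordinates live in ``[0, L)``.
    ds_positions:
        ``(N_DS, 2)`` array of danger-site centers (fixed for a run).
    repulsion_radius:
        Radius ``r`` of each disc-shaped repulsion zone (default 1).
    """

    box_size: float
    ds_positions: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    repulsion_radius: float = 1.0

    def __post_init__(self) -> None:
        if self.box_size <= 0:
            raise ValueError(f"box_size must be positive, got {self.box_size}")
        if self.repulsion_radius <= 0:
            raise ValueError(
                f"repulsion_radius must be positive, got {self.repulsion_radius}"
            )
        ds = np.asarray(self.ds_positions, dtype=float).reshape(-1, 2)
        if ds.size and (ds.min() < 0 or ds.max() >= self.box_size):
            raise ValueError("all DS coordinates must lie in [0, box_size)")
        ds.flags.writeable = False
        object.__setattr__(self, "ds_positions", ds)

    @property
    def n_ds(self) -> int:
        return len(self.ds_positions)

    @property
    def ds_density(self) -> float:
        """Areal DS density ``rho_DS = N_DS / L**2``."""
        return self.n_ds / self.box_size**2

    # -- JSON round trip (CLI --environment FILE) ---------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "L": self.box_size,
                "r": self.repulsion_radius,
                "ds": self.ds_positions.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "EnvironmentSpec":
        data = json.loads(text)
        return cls(
            box_size=float(data["L"]),
            ds_positions=np.asarray(data["ds"], dtype=float).reshape(-1, 2),
            repulsion_radius=float(data.get("r", 1.0)),
        )


def minimum_image_displacement(a, b, box_size: float) -> np.ndarray:
    """Shortest displacement from ``a`` to ``b`` on the torus.

    Each component of the result lies in ``[-L/2, L/2)``. Works on single
    points or broadcastable arrays of points.
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return (d + box_size / 2.0) % box_size - box_size / 2.0


def torus_distance(a, b, box_size: float) -> np.ndarray:
    """Euclidean distance induced by the minimum-image displacement."""
    d = minimum_image_displacement(a, b, box_size)
    return np.sqrt(np.sum(d * d, axis=-1))


def generate_random_environment(
    n_ds: int,
    box_size: float,
    repulsion_radius: float = 1.0,
    seed: int | None = None,
) -> EnvironmentSpec:
    """Uniform-random DS field: ``n_ds`` sites i.i.d. uniform over the box.

    Repulsion zones may overlap (no exclusion between sites). Reproducible
    given ``seed``.
    """
    if n_ds < 0:
        raise ValueError(f"n_ds must be non-negative, got {n_ds}")
    if box_size <= 0:
        raise ValueError(f"box_size must be positive, got {box_size}")
    rng = np.random.default_rng(seed)
    ds = rng.uniform(0.0, box_size, size=(int(n_ds), 2))
    return EnvironmentSpec(box_size, ds, repulsion_radius)


def generate_structured_environment(
    box_size: float,
    ds_density: float,
    path_center: tuple[float, float] | None = None,
    path_radius: float | None = None,
    path_width: float = 3.0,
    repulsion_radius: float = 1.0,
    seed: int | None = None,
) -> EnvironmentSpec:
    """Random DS field with an exactly DS-free circular path (annulus).

    Sites are drawn uniformly at ``ds_density`` over the whole box, then any
    site whose center falls inside the annulus ``path_radius +- path_width/2``
    around ``path_center`` is rejected (not re-drawn), so the realized global
    density is slightly below nominal. Defaults: center of the box,
    ``path_radius = L/3``, ``path_width = 3``.
    """
    if box_size <= 0:
        raise ValueError(f"box_size must be positive, got {box_size}")
    if ds_density < 0:
        raise ValueError(f"ds_density must be non-negative, got {ds_density}")
    center = (
        np.array([box_size / 2.0, box_size / 2.0])
        if path_center is None
        else np.asarray(path_center, dtype=float)
    )
    radius = box_size / 3.0 if path_radius is None else float(path_radius)
    inner = radius - path_width / 2.0
    outer = radius + path_width / 2.0
    if inner <= 0 or outer >= box_size / 2.0:
        raise ValueError(
            "annulus does not fit in the box: need "
            f"0 < {inner:.3g} and {outer:.3g} < L/2 = {box_size / 2:.3g}"
        )
    rng = np.random.default_rng(seed)
    n_nominal = int(round(ds_density * box_size**2))
    ds = rng.uniform(0.0, box_size, size=(n_nominal, 2))
    if n_nominal:
        dist = torus_distance(ds, center, box_size)
        keep = (dist < inner) | (dist > outer)
        ds = ds[keep]
    return EnvironmentSpec(box_size, ds, repulsion_radius)
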