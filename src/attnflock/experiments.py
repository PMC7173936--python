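"""Experiment orchestration: controls, parameter sweeps, reproducible seeds.

The avoidance ratio ``A`` compares each socially interacting run against a
non-interacting control on the *same* environment: solitary agents
(``gamma_s = 0``) that always respond to a repulsion zone they are inside
(no attention limit on danger detection), while informed agents keep their
directional bias. Sweeps iterate a grid over (k, rho_DS, R_inf) with
replicates, deriving one pure, collision-free seed per cell from the base
seed, so re-running a sweep reproduces the table bit for bit.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import ModelParams, SimulationResult, run_simulation
from .environment import EnvironmentSpec, generate_random_environment
from .observables import RunSummary, avoidance_ratio, summarize_run

__all__ = [
    "SweepConfig",
    "derive_seed",
    "run_noninteracting_control",
    "run_single",
    "run_sweep",
]

logger = logging.getLogger(__name__)


def derive_seed(base_seed: int, *parts) -> int:
    """Pure 31-bit seed from a base seed and arbitrary cell labels.

    Floats are canonicalized via ``repr`` so the mapping is stable across
    sessions and platforms.
    """
    key = "|".join([str(int(base_seed))] + [repr(p) for p in parts])
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def control_params(params: ModelParams) -> ModelParams:
    """Parameters of the paired non-interacting control.

    ``gamma_s = 0`` removes social interactions; ``p_direct = 1`` makes every
    agent inside a repulsion zone respond to all containing zones
    unconditionally (the attention limit no longer gates danger detection).
    With both in place the attention capacity is irrelevant to the dynamics,
    so it is pinned to ``k=1`` to keep neighbor queries cheap.
    """
    return replace(params, gamma_s=0.0, p_direct=1.0, signaling=False, k=1)


def run_noninteracting_control(
    env: EnvironmentSpec,
    params: ModelParams,
    n_agents: int | None = None,
    r_inf: float = 0.1,
    total_time: float = 600.0,
    burn_in_time: float | None = None,
    seed: int | None = None,
    return_result: bool = False,
):
    """Stationary raw avoidance A~_ni of solitary agents in ``env``.

    Returns ``A~_ni`` (or ``(A~_ni, SimulationResult)`` with
    ``return_result=True``).
    """
    result = run_simulation(
        env,
        control_params(params),
        n_agents=n_agents,
        r_inf=r_inf,
        total_time=total_time,
        burn_in_time=burn_in_time,
        seed=seed,
    )
    summary = summarize_run(result, edge_lifetimes=False)
    return (summary.A_tilde, result) if return_result else summary.A_tilde


def run_single(
    env: EnvironmentSpec,
    params: ModelParams,
    n_agents: int | None = None,
    r_inf: float = 0.1,
    total_time: float = 600.0,
    burn_in_time: float | None = None,
    seed: int | None = None,
    with_control: bool = False,
    control_seed: int | None = None,
    beta: float | None = None,
    edge_lifetimes: bool = False,
) -> tuple[RunSummary, SimulationResult]:
    """One full run (optionally with a paired control for ``A``)."""
    result = run_simulation(
        env,
        params,
        n_agents=n_agents,
        r_inf=r_inf,
        total_time=total_time,
        burn_in_time=burn_in_time,
        seed=seed,
    )
    a_ni = None
    if with_control:
        a_ni = run_noninteracting_control(
            env,
            params,
            n_agents=n_agents,
            r_inf=r_inf,
            total_time=total_time,
            burn_in_time=burn_in_time,
            seed=control_seed if control_seed is not None else derive_seed(seed or 0, "ctrl"),
        )
    summary = summarize_run(
        result, a_tilde_control=a_ni, beta=beta, edge_lifetimes=edge_lifetimes
    )
    return summary, result


@dataclass
class SweepConfig:
    """Grid specification for benchmark sweeps over (k, rho_DS, R_inf)."""

    ks: list[int] = field(default_factory=lambda: [1, 6, 24])
    ds_densities: list[float] = field(default_factory=lambda: [0.0, 0.2])
    r_infs: list[float] = field(default_factory=lambda: [0.1])
    betas: list[float] = field(default_factory=list)
    replicates: int = 3
    base_params: ModelParams = field(default_factory=ModelParams)
    n_agents: int = 625
    box_size: float = 25.0
    total_time: float = 600.0
    burn_in_time: float | None = None
    base_seed: int = 0
    with_controls: bool = True
    output_dir: str | None = None


def run_sweep(cfg: SweepConfig) -> pd.DataFrame:
    """Run the full grid; one row per (k, rho_DS, R_inf, replicate).

    Control runs are shared across ``k`` within a (rho_DS, R_inf, replicate)
    cell (the control has no social interactions, so ``k`` is irrelevant to
    it) and use the same environment realization as the main runs. Fitness
    columns ``F_beta=<b>`` are evaluated post hoc from stored (C, A). Cells
    already present in ``<output_dir>/results.csv`` are skipped; individual
    cell failures are logged and do not abort the sweep.
    """
    out_path = None
    existing = None
    if cfg.output_dir is not None:
        out_path = Path(cfg.output_dir) / "results.csv"
        if out_path.exists():
            existing = pd.read_csv(out_path)

    rows: list[dict] = []
    controls: dict[tuple, float] = {}
    for rho in cfg.ds_densities:
        for rep in range(cfg.replicates):
            n_ds = int(round(rho * cfg.box_size**2))
            env = generate_random_environment(
                n_ds,
                cfg.box_size,
                seed=derive_seed(cfg.base_seed, "env", rho, rep),
            )
            for r_inf in cfg.r_infs:
                ctrl_key = (rho, r_inf, rep)
                for k in cfg.ks:
                    if existing is not None and (
                        (existing["k"] == k)
                        & (existing["rho_ds"] == rho)
                        & (existing["r_inf"] == r_inf)
                        & (existing["replicate"] == rep)
                    ).any():
                        continue
                    try:
                        row = _run_cell(cfg, env, k, rho, r_inf, rep, controls)
                    except Exception:
                        logger.exception(
                            "cell failed: k=%s rho=%s r_inf=%s rep=%s",
                            k, rho, r_inf, rep,
                        )
                        continue
                    rows.append(row)

    table = pd.DataFrame(rows)
    if existing is not None and len(existing):
        table = pd.concat([existing, table], ignore_index=True)
    if out_path is not None and len(table):
        out_path.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_path, index=False)
    return table


def _run_cell(
    cfg: SweepConfig,
    env: EnvironmentSpec,
    k: int,
    rho: float,
    r_inf: float,
    rep: int,
    controls: dict,
) -> dict:
    params = replace(cfg.base_params, k=k)
    seed = derive_seed(cfg.base_seed, "run", k, rho, r_inf, rep)
    result = run_simulation(
        env,
        params,
        n_agents=cfg.n_agents,
        r_inf=r_inf,
        total_time=cfg.total_time,
        burn_in_time=cfg.burn_in_time,
        seed=seed,
    )
    a_ni = None
    if cfg.with_controls:
        ctrl_key = (rho, r_inf, rep)
        if ctrl_key not in controls:
            controls[ctrl_key] = run_noninteracting_control(
                env,
                cfg.base_params,
                n_agents=cfg.n_agents,
                r_inf=r_inf,
                total_time=cfg.total_time,
                burn_in_time=cfg.burn_in_time,
                seed=derive_seed(cfg.base_seed, "ctrl", rho, r_inf, rep),
            )
        a_ni = controls[ctrl_key]
    summary = summarize_run(result, a_tilde_control=a_ni, edge_lifetimes=True)
    row = {
        "k": k,
        "rho_ds": rho,
        "r_inf": r_inf,
        "replicate": rep,
        "seed": seed,
        **summary.to_dict(),
        "A_tilde_control": a_ni,
    }
    if summary.A is not None:
        for beta in cfg.betas:
            row[f"F_beta={beta:g}"] = summary.C + beta * (summary.A - 1.0)
    return row
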