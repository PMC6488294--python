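"""Data tables behind the four standard figures.

Each function emits plain CSV/JSON with the quantities the corresponding
figure plots; ``scale`` shrinks generation counts, replicate counts and grid
resolutions proportionally for desk-scale runs (1.0 reproduces the full
study conditions).  Plotting is deliberately left to the user.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .abm import SimulationConfig, run_simulation
from .adaptive_dynamics import ess_vs_benefit_curve, find_singular_points, pip_matrix
from .empathy_abm import EmpathyEvolutionConfig, run_empathy_evolution
from .io import write_json, write_results
from .norms import GameParams
from .replicator import (
    basin_map,
    edge_equilibrium_alld_disc,
    simple_standing_mixed_equilibrium,
)

__all__ = ["reproduce_figure_tables"]

_E_GRID = (0.0, 0.5, 1.0)
_NORMS_E_SENSITIVE = ("SJ", "SS", "SH")


def _fig2(scale, out_dir, seed, force):
    """Basins of attraction and strategic equilibria per norm and empathy level."""
    params = GameParams()
    res = max(10, int(round(50 * scale)))
    cell_frames, eq_rows, outputs = [], [], []
    for norm in ("SJ", "SS", "SC", "SH"):
        for E in _E_GRID:
            bm = basin_map(norm, params, E, grid_resolution=res)
            cells = bm.cells.copy()
            cells.insert(0, "norm", norm)
            cells.insert(1, "E", E)
            cell_frames.append(cells)
            row = {"norm": norm, "E": E, "basin_fraction": bm.basin_fraction}
            if norm in _NORMS_E_SENSITIVE:
                row["unstable_edge_fZ"] = edge_equilibrium_alld_disc(norm, params, E)
            if norm == "SS":
                row["mixed_equilibrium_fZ"] = simple_standing_mixed_equilibrium(params, E)
            eq_rows.append(row)
    cells_path = out_dir / "fig2_basin_cells.csv"
    all_cells = pd.concat(cell_frames, ignore_index=True)
    write_results(all_cells, "basin_cells", cells_path, force=force)
    eq_path = out_dir / "fig2_equilibria.csv"
    pd.DataFrame(eq_rows).to_csv(eq_path, index=False)
    outputs += [cells_path, eq_path]
    return outputs


def _fig3(scale, out_dir, seed, force):
    """Mean cooperation versus empathy for each norm (strategy Monte Carlo)."""
    params = GameParams()
    gens = max(1000, int(round(150_000 * scale)))
    reps = max(1, int(round(50 * scale)))
    rows = []
    for norm in ("SJ", "SS", "SC", "SH"):
        for E in np.linspace(0.0, 1.0, 5):
            cfg = SimulationConfig(norm=norm, params=params, E=float(E), N=100,
                                   w=1.0, mu=0.001, generations=gens, burn_in=0,
                                   replicates=reps, seed=seed, thin=max(1, gens // 500))
            res = run_simulation(cfg)
            rows.append({"norm": norm, "E": float(E),
                         "mean_cooperation": res.mean_cooperation,
                         "sem_cooperation": res.sem_cooperation,
                         "generations": gens, "replicates": reps})
    path = out_dir / "fig3_cooperation_vs_empathy.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return [path]


def _fig4(scale, out_dir, seed, force):
    """Pairwise invasibility plots plus empathy-evolution trajectories."""
    params = GameParams()
    res = 41
    gens = max(1000, int(round(50_000 * scale)))
    outputs = []
    pip_frames, sp_payload = [], {}
    for norm in _NORMS_E_SENSITIVE:
        es, signs = pip_matrix(norm, params, resolution=res)
        pip_frames.append(pd.DataFrame({
            "norm": norm,
            "E_resident": np.repeat(es, res),
            "E_invader": np.tile(es, res),
            "sign_W": signs.T.ravel(),
        }))
        sp_payload[norm] = [
            {"E_star": p.E_star, "stability": p.stability}
            for p in find_singular_points(norm, params)
        ]
    pip_path = out_dir / "fig4_pip.csv"
    write_results(pd.concat(pip_frames, ignore_index=True), "pip", pip_path, force=force)
    sp_path = out_dir / "fig4_singular_points.json"
    write_json(sp_payload, sp_path, force=force)
    outputs += [pip_path, sp_path]

    traj_rows = []
    for norm, e_init in (("SJ", 0.9), ("SS", 0.5), ("SH", 0.05)):
        cfg = EmpathyEvolutionConfig(norm=norm, params=params, N=100, generations=gens,
                                     replicates=3, seed=seed, E_init=e_init,
                                     thin=max(1, gens // 200))
        result = run_empathy_evolution(cfg)
        for r in range(cfg.replicates):
            traj_rows.append(pd.DataFrame({
                "norm": norm, "replicate": r,
                "generation": np.arange(0, gens, max(1, gens // 500)),
                "mean_E": result.mean_E[r, ::max(1, gens // 500)],
            }))
    traj_path = out_dir / "fig4_empathy_trajectories.csv"
    pd.concat(traj_rows, ignore_index=True).to_csv(traj_path, index=False)
    outputs.append(traj_path)
    return outputs


def _fig5(scale, out_dir, seed, force):
    """Singular values of empathy versus the benefit-cost ratio."""
    params = GameParams()
    grid = np.linspace(1.5, 10.0, 18)
    tables = [ess_vs_benefit_curve(norm, params, grid) for norm in _NORMS_E_SENSITIVE]
    path = out_dir / "fig5_singular_points_vs_bc.csv"
    write_results(pd.concat(tables, ignore_index=True), "ess_scan", path, force=force)
    return [path]


def reproduce_figure_tables(
    figure_id: int, scale: float, out_dir: Path, seed: int, *, force: bool = False
) -> list[Path]:
    """Emit the data tables for one of the standard figures (2-5)."""
    if figure_id not in (2, 3, 4, 5):
        raise ValueError("figure_id must be one of 2, 3, 4, 5")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return {2: _fig2, 3: _fig3, 4: _fig4, 5: _fig5}[figure_id](scale, out_dir, seed, force)
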