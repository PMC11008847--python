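"""Densification and adhesion sweeps over the four-cell colony.

Density is controlled solely by the available substrate length; each run
time-evolves the colony for a 24 h-equivalent and summarizes the final
hour.  The default grid targets densities of roughly 1.5-9 Arb: with four
cells fully covering a substrate of length L model units,
Arb = (400 / (10 L))^2 / 1000 = 160 / L^2.
"""

from __future__ import annotations

import math

import pandas as pd

from .engine import ScenarioConfig, hours_to_steps, run_scenario
from .metrics import interior_cell_indices, ratio_turning_density, transition_density
from .params import ModelParams

#: target densities (Arb) of the default 12-point substrate-length grid
DEFAULT_SWEEP_ARB = (1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.75, 5.5, 6.25, 7.0,
                     8.0, 9.0)
#: most confined substrate of the sub-7-Arb grid (used for adhesion sweeps)
HIGH_DENSITY_ARB = 6.5


def substrate_length_for_arb(arb: float, n_cells: int = 4) -> float:
    """Substrate length (model units) whose full coverage by ``n_cells``
    yields the target density in Arb."""
    cells_per_mm = math.sqrt(arb * 1000.0)
    return n_cells * 100.0 / cells_per_mm


def default_substrate_lengths(n_cells: int = 4) -> list[float]:
    return [substrate_length_for_arb(a, n_cells) for a in DEFAULT_SWEEP_ARB]


def run_density_point(params: ModelParams, substrate_length: float,
                      hours: float = 24.0, seed: int = 0,
                      record_stride: int = 250,
                      average_window_h: float = 1.0) -> dict:
    """One densification run; summarize metrics over the final window."""
    config = ScenarioConfig(scenario="four_cell_confined",
                            substrate_length=substrate_length,
                            total_steps=hours_to_steps(hours, params),
                            record_stride=record_stride,
                            seed=seed, store_frames=False, params=params)
    result = run_scenario(config)
    df = result.metrics_frame()
    t_end = df["time_h"].max()
    win = df[df["time_h"] >= t_end - average_window_h]
    interior = set(
        interior_cell_indices(result.final_state.cells).tolist())
    win_int = win[win["cell"].isin(interior)]
    return {
        "substrate_length": substrate_length,
        "density_arb": float(win["density_arb"].mean()),
        "density_cells_per_mm2": float(win["density_cells_per_mm2"].mean()),
        "mean_f_cs": float(win_int["f_cs"].mean()),
        "mean_f_cc": float(win_int["f_cc"].mean()),
        # interior cells only: colony-edge cells bulge over the substrate
        # ends, truncating their basal surface and distorting the ratio
        "mean_apical_basal": float(win_int["apical_basal"].mean()),
        "label": win.iloc[-1]["label"],
    }


def densification_sweep(params: ModelParams,
                        substrate_lengths: list[float] | None = None,
                        hours: float = 24.0, seed: int = 0,
                        record_stride: int = 250) -> pd.DataFrame:
    """Run the colony over a substrate-length grid; one summary row per
    run, sorted by realized density."""
    if substrate_lengths is None:
        substrate_lengths = default_substrate_lengths()
    rows = [run_density_point(params, L, hours=hours, seed=seed,
                              record_stride=record_stride)
            for L in substrate_lengths]
    df = pd.DataFrame(rows).sort_values("density_arb").reset_index(drop=True)
    return df


def sweep_transition_density(sweep_df: pd.DataFrame,
                             cc_threshold: float = 0.10,
                             column: str = "density_arb") -> float | None:
    """Density of the Immature -> Intermediate crossing in a sweep table."""
    pairs = list(zip(sweep_df[column], sweep_df["mean_f_cc"]))
    return transition_density(pairs, cc_threshold)


def sweep_ratio_turning(sweep_df: pd.DataFrame) -> float:
    """Density (Arb) where the apical:basal ratio trend turns downward."""
    return ratio_turning_density(sweep_df["density_arb"].to_numpy(),
                                 sweep_df["mean_apical_basal"].to_numpy())


def adhesion_sweep(params: ModelParams, mode: str,
                   gamma_cs_values: list[float],
                   substrate_length: float | None = None,
                   hours: float = 24.0, seed: int = 0) -> pd.DataFrame:
    """Mean cell-cell connection fraction at the highest density, for each
    cell-substrate adhesion strength under a given spreading-scaling mode."""
    if substrate_length is None:
        substrate_length = substrate_length_for_arb(HIGH_DENSITY_ARB)
    rows = []
    for g in gamma_cs_values:
        p = params.replace(gamma_cs=g, spreading_mode=mode)
        row = run_density_point(p, substrate_length, hours=hours, seed=seed)
        row["gamma_cs"] = g
        row["spreading_mode"] = mode
        rows.append(row)
    return pd.DataFrame(rows)


def min_adhesion_for_intermediate(adhesion_df: pd.DataFrame,
                                  cc_threshold: float = 0.10) -> float | None:
    """Smallest gamma_cs whose run still reaches the Intermediate
    threshold; None if none does."""
    ok = adhesion_df[adhesion_df["mean_f_cc"] >= cc_threshold]
    if ok.empty:
        return None
    return float(ok["gamma_cs"].min())
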