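"""Explicit-Euler time stepping, scenario setup, and the step orchestration.

Overdamped node dynamics: F = beta * v, integrated as
p <- p + dt * F / beta with dt = 1 in model units; ~750 timesteps
correspond to one hour in culture.  Per step, in order: (1) cortical
remodeling, (2) division program updates and due divisions, (3) bond
recomputation and contact flags, (4) adhesion feedback (effective
parameters from current contacts and the previous step's substrate-bond
counts), (5) force summation, (6) the Euler move (substrate fixed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import mechanics
from .geometry import (Cell, Substrate, make_circular_cell, make_substrate,
                       regular_polygon_radius, standard_node_spacing)
from .mechanics import BondSet, EffectiveParams
from .metrics import MetricsRecord, frame_metrics
from .params import ModelParams
from .remodel import (divide_cell, remodel_cortex, sample_initial_cycles,
                      update_division_program)

SCENARIOS = ("single_cell_spreading", "single_cell_no_spreading",
             "two_cell", "three_cell_division", "four_cell_confined")


def steps_to_hours(n_steps: float, params: ModelParams) -> float:
    """Convert a step count to culture hours (750 steps ~ 1 h)."""
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    return n_steps / params.steps_per_hour


def hours_to_steps(hours: float, params: ModelParams) -> int:
    return int(round(hours * params.steps_per_hour))


@dataclass
class ScenarioConfig:
    """Everything needed to reproduce a run."""

    scenario: str = "four_cell_confined"
    n_cells: int = 4
    n_nodes: int = 100
    substrate_length: float = 8.0
    drop_height: float | None = None      # default: one cell diameter
    cell_spacing: float | None = None     # default: cortices just out of d_cc
    total_steps: int = 18000
    record_stride: int = 50
    seed: int = 0
    spreading: bool = True
    store_frames: bool = True
    cycle_mode: str = "none"              # none | central | uniform
    central_cycle_hours: float = 2.0      # cycle of the dividing central cell
    daughters_divide: bool = False
    daughter_cycle_hours: float = 4.0
    params: ModelParams = field(default_factory=ModelParams)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.total_steps < 1:
            raise ValueError("total_steps must be >= 1")
        if self.cycle_mode not in ("none", "central", "uniform"):
            raise ValueError("cycle_mode must be none, central or uniform")
        presets = {"single_cell_spreading": (1, True),
                   "single_cell_no_spreading": (1, False),
                   "two_cell": (2, True),
                   "three_cell_division": (3, True),
                   "four_cell_confined": (4, True)}
        n, spread = presets[self.scenario]
        self.n_cells = n
        if self.scenario == "single_cell_no_spreading":
            self.spreading = False
        if self.scenario == "three_cell_division" and self.cycle_mode == "none":
            self.cycle_mode = "central"


@dataclass
class DivisionEvent:
    step: int
    parent: int
    parent_area: float
    daughter_areas: tuple[float, float]


@dataclass
class Frame:
    step: int
    time_h: float
    cells: list[np.ndarray]
    bonds: BondSet


@dataclass
class SimulationState:
    cells: list[Cell]
    substrate: Substrate
    params: ModelParams
    config: ScenarioConfig
    rng: np.random.Generator
    step_index: int = 0
    bonds: BondSet | None = None
    effective: EffectiveParams | None = None
    prev_N_sub: np.ndarray | None = None
    max_displacement: float = 0.0
    division_events: list[DivisionEvent] = field(default_factory=list)

    @property
    def time_h(self) -> float:
        return steps_to_hours(self.step_index * self.params.dt, self.params)


DEFAULT_CELL_SPACING = 2.0  # model units (20 um between plated cell centers)


def initial_state(config: ScenarioConfig) -> SimulationState:
    """Round cells dropped above a centered substrate.

    Cells start one diameter above the substrate with centers 2 length
    units (20 um) apart, sparse enough that each cell flattens on the
    substrate before first touching its neighbors, as cells do on plating;
    under confinement the spacing shrinks so the colony fits the substrate.
    """
    params = config.params
    n = config.n_cells
    r = regular_polygon_radius(params.A0, config.n_nodes)
    diameter = 2.0 * r
    spacing = config.cell_spacing
    if spacing is None:
        if config.scenario in ("two_cell", "three_cell_division"):
            # cells landing in proximity: cortices just outside d_cc
            spacing = diameter + params.d_cc + 0.01
        else:
            spacing = DEFAULT_CELL_SPACING
        if n > 1:
            fit = (config.substrate_length - diameter - 0.05) / (n - 1)
            spacing = min(spacing, max(fit, 0.3 * diameter))
    drop = config.drop_height if config.drop_height is not None else diameter
    x0 = -0.5 * spacing * (n - 1)
    rng = np.random.default_rng(config.seed)

    if config.cycle_mode == "uniform":
        cycles = sample_initial_cycles(n, rng)
    elif config.cycle_mode == "central":
        cycles = np.full(n, math.inf)
        cycles[n // 2] = config.central_cycle_hours
    else:
        cycles = np.full(n, math.inf)

    cells = [make_circular_cell((x0 + i * spacing, drop + r), params.A0,
                                config.n_nodes, cycle_length=float(cycles[i]))
             for i in range(n)]
    half = 0.5 * config.substrate_length
    substrate = make_substrate(-half, half, standard_node_spacing(
        params.A0, config.n_nodes))
    state = SimulationState(cells=cells, substrate=substrate, params=params,
                            config=config, rng=rng)
    state.effective = EffectiveParams.base(cells, params)
    state.prev_N_sub = np.zeros(n, dtype=np.intp)
    return state


def _handle_divisions(state: SimulationState) -> None:
    params = state.params
    cfg = state.config
    out_cells: list[Cell] = []
    new_prev: list[int] = []
    divided = False
    for i, cell in enumerate(state.cells):
        update_division_program(cell, params.A0)
        if math.isfinite(cell.cycle_length) and cell.age >= cell.cycle_length:
            daughter_cycle = (cfg.daughter_cycle_hours if cfg.daughters_divide
                              else math.inf)
            parent_area = cell.area()
            d1, d2 = divide_cell(cell, params.A0, daughter_cycle)
            state.division_events.append(DivisionEvent(
                step=state.step_index, parent=i, parent_area=parent_area,
                daughter_areas=(d1.area(), d2.area())))
            out_cells.extend([d1, d2])
            new_prev.extend([0, 0])
            divided = True
        else:
            out_cells.append(cell)
            new_prev.append(int(state.prev_N_sub[i]))
    if divided:
        state.cells = out_cells
        state.prev_N_sub = np.array(new_prev, dtype=np.intp)
        state.effective = EffectiveParams.base(out_cells, params)


def step(state: SimulationState) -> SimulationState:
    """Advance the system by one explicit-Euler timestep (in place)."""
    params = state.params
    # (1) cortical remodeling
    for cell in state.cells:
        remodel_cortex(cell)
    # (2) division program / due divisions
    _handle_divisions(state)
    cells = state.cells
    # (3) bonds and contact flags (matched with last step's effective d_cc)
    bonds = mechanics.build_bond_set(cells, state.substrate, params,
                                     state.effective)
    # (4) adhesion feedback from current contacts and previous N_sub
    effective = mechanics.effective_adhesion_params(
        cells, bonds.has_cc_contact(), state.prev_N_sub, params)
    # (5) force summation (batched over the concatenated node array)
    counts = np.array([c.n_nodes for c in cells], dtype=np.intp)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(np.intp)
    pos = np.concatenate([c.nodes for c in cells])
    F = mechanics.assemble_forces_batch(
        cells, pos, starts, counts, state.substrate, params, bonds,
        effective, spreading_enabled=state.config.spreading)
    if not np.all(np.isfinite(F)):
        raise RuntimeError(
            f"non-finite force at step {state.step_index}; "
            f"cell areas: {[c.area() for c in cells]}")
    # (6) Euler move
    scale = params.dt / params.beta
    disp = scale * F
    max_disp = float(np.abs(disp).max()) if len(disp) else 0.0
    pos += disp
    dt_h = params.dt / params.steps_per_hour
    for i, cell in enumerate(cells):
        cell.nodes = pos[starts[i]:starts[i] + counts[i]]
        cell.age += dt_h
    state.bonds = bonds
    state.effective = effective
    state.prev_N_sub = bonds.N_sub
    state.max_displacement = max(state.max_displacement, max_disp)
    state.step_index += 1
    return state


@dataclass
class SimResult:
    config: ScenarioConfig
    frames: list[Frame]
    metrics: list[MetricsRecord]
    division_events: list[DivisionEvent]
    final_state: SimulationState

    def metrics_frame(self):
        """Metrics as a tidy pandas DataFrame (one row per cell per frame)."""
        import pandas as pd
        return pd.DataFrame([vars(m) for m in self.metrics])


def run_scenario(config: ScenarioConfig,
                 progress: Callable[[SimulationState], None] | None = None,
                 ) -> SimResult:
    """Run a configured scenario, recording frames and per-frame metrics."""
    state = initial_state(config)
    frames: list[Frame] = []
    records: list[MetricsRecord] = []

    def record() -> None:
        if state.bonds is None:
            return
        t = state.time_h
        if config.store_frames:
            frames.append(Frame(step=state.step_index, time_h=t,
                                cells=[c.nodes.copy() for c in state.cells],
                                bonds=state.bonds))
        records.extend(frame_metrics(state.cells, state.bonds, t,
                                     config.params.cc_threshold))

    for i in range(config.total_steps):
        step(state)
        if state.step_index % config.record_stride == 0:
            record()
            if progress is not None:
                progress(state)
    if state.step_index % config.record_stride != 0:
        record()
    return SimResult(config=config, frames=frames, metrics=records,
                     division_events=state.division_events,
                     final_state=state)


def relax_isolated_cell(cell: Cell, params: ModelParams,
                        max_steps: int = 120000,
                        tol: float = 1e-10) -> tuple[Cell, int]:
    """Relax a single cell under internal forces only (no substrate,
    gravity or spreading) until node displacements fall below ``tol``.

    Returns the relaxed cell and the number of steps taken.  The analytic
    fixed point is a circle of area A* = A0 - 2 pi k_L / k_A.
    """
    scale = params.dt / params.beta
    for i in range(max_steps):
        remodel_cortex(cell)
        F = mechanics.internal_forces(cell, params)
        disp = scale * F
        cell.nodes += disp
        if float(np.abs(disp).max()) < tol:
            return cell, i + 1
    return cell, max_steps
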