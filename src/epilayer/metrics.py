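"""Layer measurements and architecture classification.

The proportion of a cell's nodes participating in cell-substrate or
cell-cell adhesion proxies the basal and lateral interface lengths.  A
layer whose interior cells commit on average >= 10% of their nodes to
cell-cell adhesion is classified Intermediate; below that, Immature.

Density conventions: the simulation is a 2D cross-section, so density is
reported in arbitrary units (Arb) obtained by scaling the linear cell
density: Arb = (cells per mm)^2 / 1000, anchored by the correspondence
between ~7 Arb in the model and ~7e3 cells/mm^2 in MDCK culture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import Cell
from .mechanics import BondSet
from .params import UM_PER_LENGTH_UNIT

IMMATURE = "Immature"
INTERMEDIATE = "Intermediate"

#: scaling of (cells/mm)^2 into the model's arbitrary density units
ARB_PER_CELLS_PER_MM2 = 1.0 / 1000.0


def connection_fractions(cell: Cell, cell_index: int,
                         bonds: BondSet) -> tuple[float, float]:
    """(f_cs, f_cc): fractions of the cell's nodes holding at least one
    substrate bond / attractive cell-cell bond."""
    n = cell.n_nodes
    f_cs = bonds.substrate_bonded_mask(cell_index, n).sum() / n
    f_cc = bonds.cc_bonded_mask(cell_index, n).sum() / n
    return float(f_cs), float(f_cc)


def occupied_span(cells: list[Cell], bonds: BondSet) -> float:
    """X-extent between the outermost substrate-bonded cell nodes."""
    if bonds.n_substrate_bonds == 0:
        raise ValueError("no substrate contact: occupied span undefined")
    xs = []
    for c in np.unique(bonds.sub_cell):
        sel = bonds.sub_cell == c
        xs.append(cells[c].nodes[bonds.sub_node[sel], 0])
    allx = np.concatenate(xs)
    return float(allx.max() - allx.min())


def layer_density(cells: list[Cell],
                  bonds: BondSet) -> tuple[float, float, float]:
    """(linear density, Arb, cells/mm^2) of the layer.

    Linear density is cells per model length unit over the occupied span;
    cells/mm = 1000/UM_PER_LENGTH_UNIT * linear; cells/mm^2 is its square
    (isotropic in-plane packing); Arb = cells/mm^2 / 1000.
    """
    span = occupied_span(cells, bonds)
    if span <= 0:
        raise ValueError("degenerate occupied span")
    linear = len(cells) / span
    cells_per_mm = linear * 1000.0 / UM_PER_LENGTH_UNIT
    cells_per_mm2 = cells_per_mm ** 2
    return linear, cells_per_mm2 * ARB_PER_CELLS_PER_MM2, cells_per_mm2


def apical_basal_ratio(cell: Cell, cell_index: int, bonds: BondSet) -> float:
    """Apical / basal surface length of one cell.

    Basal length: polyline length over edges whose endpoints both hold
    substrate bonds.  Apical length: polyline length over edges whose
    endpoints are free of both substrate and cell-cell bonds (surfaces are
    defined by exclusion from cell-cell borders).
    """
    n = cell.n_nodes
    sub = bonds.substrate_bonded_mask(cell_index, n)
    if not sub.any():
        raise ValueError("cell has no substrate bonds: ratio undefined")
    cc = bonds.cc_bonded_mask(cell_index, n)
    nxt = np.roll(cell.nodes, -1, axis=0)
    el = np.hypot(nxt[:, 0] - cell.nodes[:, 0], nxt[:, 1] - cell.nodes[:, 1])
    sub_next = np.roll(sub, -1)
    cc_next = np.roll(cc, -1)
    basal = float(el[sub & sub_next].sum())
    apical_mask = ~sub & ~cc & ~sub_next & ~cc_next
    apical = float(el[apical_mask].sum())
    if basal <= 0:
        raise ValueError("zero basal length: ratio undefined")
    return apical / basal


def interior_cell_indices(cells: list[Cell]) -> np.ndarray:
    """All cells except the leftmost and rightmost (by centroid x).

    Colony edges are Immature by construction, so edge cells are excluded
    from the classification mean (they still count toward density).
    """
    cx = np.array([c.centroid()[0] for c in cells])
    if len(cells) <= 2:
        return np.arange(len(cells))
    order = np.argsort(cx)
    return np.sort(order[1:-1])


def classify_architecture(mean_f_cc: float,
                          cc_threshold: float = 0.10) -> str:
    """Immature below the cell-cell connection threshold, Intermediate at
    or above it (the boundary value classifies Intermediate)."""
    return INTERMEDIATE if mean_f_cc >= cc_threshold else IMMATURE


def shape_index(circ: float) -> float:
    """Shape index S0 = sqrt(4 pi / circularity) = perimeter / sqrt(area).

    3.81 predicts jamming in 2D vertex models; a circle gives sqrt(4 pi).
    """
    if not 0.0 < circ <= 1.0:
        raise ValueError("circularity must lie in (0, 1]")
    return math.sqrt(4.0 * math.pi / circ)


def transition_density(sweep: list[tuple[float, float]],
                       cc_threshold: float = 0.10) -> float | None:
    """Density of the first crossing of the cell-cell connection threshold.

    ``sweep`` is a list of (density, mean f_cc) sorted by density.  Linear
    interpolation between the bracketing grid points; None if the
    threshold is never reached.
    """
    dens = [d for d, _ in sweep]
    if any(b < a for a, b in zip(dens, dens[1:])):
        raise ValueError("sweep must be sorted by density")
    prev_d, prev_f = None, None
    for d, f in sweep:
        if f >= cc_threshold:
            if prev_d is None or prev_f is None or f == prev_f:
                return float(d)
            t = (cc_threshold - prev_f) / (f - prev_f)
            return float(prev_d + t * (d - prev_d))
        prev_d, prev_f = d, f
    return None


def ratio_turning_density(densities: np.ndarray,
                          ratios: np.ndarray) -> float:
    """Density at which the apical:basal ratio trend turns from increasing
    to decreasing, via a parabolic fit through the peak grid point and its
    neighbors (falls back to the grid argmax at the sweep ends)."""
    densities = np.asarray(densities, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    order = np.argsort(densities)
    d = densities[order]
    r = ratios[order]
    k = int(np.argmax(r))
    if k == 0 or k == len(r) - 1:
        return float(d[k])
    x0, x1, x2 = d[k - 1], d[k], d[k + 1]
    y0, y1, y2 = r[k - 1], r[k], r[k + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:  # no local maximum; stay on the grid
        return float(x1)
    peak = -b / (2.0 * a)
    return float(min(max(peak, x0), x2))


@dataclass
class MetricsRecord:
    """Per-cell measurements at one recorded frame."""

    time_h: float
    cell: int
    f_cs: float
    f_cc: float
    density_linear: float
    density_arb: float
    density_cells_per_mm2: float
    apical_basal: float
    label: str


def frame_metrics(cells: list[Cell], bonds: BondSet, time_h: float,
                  cc_threshold: float = 0.10) -> list[MetricsRecord]:
    """Metrics rows (one per cell) for a single frame."""
    try:
        linear, arb, per_mm2 = layer_density(cells, bonds)
    except ValueError:
        linear = arb = per_mm2 = math.nan
    interior = set(interior_cell_indices(cells).tolist())
    fcc_interior = []
    rows = []
    for i, c in enumerate(cells):
        f_cs, f_cc = connection_fractions(c, i, bonds)
        if i in interior:
            fcc_interior.append(f_cc)
        try:
            ab = apical_basal_ratio(c, i, bonds)
        except ValueError:
            ab = math.nan
        rows.append((i, f_cs, f_cc, ab))
    mean_fcc = float(np.mean(fcc_interior)) if fcc_interior else math.nan
    label = (classify_architecture(mean_fcc, cc_threshold)
             if not math.isnan(mean_fcc) else IMMATURE)
    return [MetricsRecord(time_h=time_h, cell=i, f_cs=f_cs, f_cc=f_cc,
                          density_linear=linear, density_arb=arb,
                          density_cells_per_mm2=per_mm2, apical_basal=ab,
                          label=label)
            for (i, f_cs, f_cc, ab) in rows]
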