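"""Cortical remodeling and the cell-division program.

Remodeling keeps the cortex discretization approximately uniform: edges
longer than twice the reference node spacing are bisected, and edges
shorter than half of it lose the endpoint closest to its other neighbor.
The reference spacing is fixed at construction so stretching cannot drift
the target discretization.

Division: over the final hour of its cycle a cell linearly ramps its
preferred area from A0 to 2 A0 and ceases cell-cell adhesion; it then
splits along the chord between its topmost and bottommost nodes (planar,
apical-basal division) and the daughters remesh the cytokinetic plane.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .geometry import MIN_NODES, Cell, polygon_signed_area

GROWTH_WINDOW_HOURS = 1.0


def remodel_cortex(cell: Cell) -> Cell:
    """One pass of node insertion/removal over the cell's edges (in place).

    Edge > 2 * ref spacing -> insert the edge midpoint.  Edge < 0.5 * ref
    spacing -> remove whichever endpoint of that edge is closer to its other
    neighbor.  Removals that would drop the node count below the minimum
    are skipped with a warning.
    """
    nodes = cell.nodes
    n = len(nodes)
    ref = cell.node_ref_spacing
    ex = np.empty(n)
    ez = np.empty(n)
    ex[:-1] = nodes[1:, 0] - nodes[:-1, 0]
    ex[-1] = nodes[0, 0] - nodes[-1, 0]
    ez[:-1] = nodes[1:, 1] - nodes[:-1, 1]
    ez[-1] = nodes[0, 1] - nodes[-1, 1]
    el = np.sqrt(ex * ex + ez * ez)

    if not (bool((el > 2.0 * ref).any()) or bool((el < 0.5 * ref).any())):
        return cell
    long_edges = np.nonzero(el > 2.0 * ref)[0]
    short_edges = np.nonzero(el < 0.5 * ref)[0]

    # decide removals on the original node list
    to_delete: set[int] = set()
    if short_edges.size:
        prv_el = np.roll(el, 1)  # prv_el[j] = length of edge (j-1, j)
        for e in short_edges:
            a, b = e, (e + 1) % n
            if a in to_delete or b in to_delete:
                continue
            if n - len(to_delete) <= MIN_NODES:
                warnings.warn("skipping node removal: cell at minimum "
                              "node count", RuntimeWarning, stacklevel=2)
                continue
            # endpoint closest to its *other* neighbor goes
            da = prv_el[a]          # a's distance to node a-1
            db = el[b]              # b's distance to node b+1
            to_delete.add(a if da <= db else b)

    # insertions only on edges whose endpoints survive
    pieces: list[np.ndarray] = []
    long_set = set(long_edges.tolist())
    for j in range(n):
        if j in to_delete:
            continue
        pieces.append(nodes[j])
        k = (j + 1) % n
        if j in long_set and k not in to_delete:
            pieces.append(0.5 * (nodes[j] + nodes[k]))
    cell.nodes = np.array(pieces)
    return cell


def remodel_until_stable(cell: Cell, max_rounds: int = 60) -> Cell:
    """Repeat remodeling passes until the node count stops changing."""
    for _ in range(max_rounds):
        before = cell.n_nodes
        remodel_cortex(cell)
        if cell.n_nodes == before:
            break
    return cell


def update_division_program(cell: Cell, params_A0: float) -> None:
    """Advance the growth/adhesion state of a proliferative cell (in place).

    During the final hour of the cycle the preferred area ramps linearly
    from A0 to 2 A0 and the cell's gamma_cc is set to zero (adhesion
    cessation); outside that window the cell is left untouched.
    """
    if not math.isfinite(cell.cycle_length):
        return
    into_window = cell.age - (cell.cycle_length - GROWTH_WINDOW_HOURS)
    if into_window < 0:
        return
    tau = min(into_window / GROWTH_WINDOW_HOURS, 1.0)
    cell.preferred_area = params_A0 * (1.0 + tau)
    cell.gamma_cc = 0.0
    cell.dividing = True


def divide_cell(cell: Cell, base_area: float,
                daughter_cycle_length: float = math.inf) -> tuple[Cell, Cell]:
    """Split a grown cell along the chord from its top to its bottom node.

    Each daughter keeps its arc of the parent polyline plus the two chord
    endpoints, then remeshes until the cytokinetic plane is populated at
    roughly the reference spacing.  Daughters restart at age 0 with
    preferred area ``base_area``.
    """
    nodes = cell.nodes
    n = len(nodes)
    top = int(np.argmax(nodes[:, 1]))
    bot = int(np.argmin(nodes[:, 1]))
    if top == bot:
        warnings.warn("degenerate division axis; division aborted",
                      RuntimeWarning, stacklevel=2)
        raise ValueError("top and bottom nodes coincide")

    def arc(a: int, b: int) -> np.ndarray:
        if a <= b:
            return nodes[a:b + 1]
        return np.vstack([nodes[a:], nodes[:b + 1]])

    halves = []
    for a, b in ((top, bot), (bot, top)):
        poly = arc(a, b)
        if len(poly) < 3 or abs(polygon_signed_area(poly)) <= 0:
            warnings.warn("degenerate daughter polygon; division aborted",
                          RuntimeWarning, stacklevel=2)
            raise ValueError("division produced a degenerate daughter")
        halves.append(poly)

    daughters = []
    for poly in halves:
        # pad degenerate tiny polygons up to the minimum node count by
        # subdividing the longest edges
        d = Cell(nodes=_ensure_min_nodes(poly),
                 preferred_area=base_area,
                 node_ref_spacing=cell.node_ref_spacing,
                 cycle_length=daughter_cycle_length,
                 age=0.0)
        remodel_until_stable(d)
        daughters.append(d)
    return daughters[0], daughters[1]


def _ensure_min_nodes(poly: np.ndarray) -> np.ndarray:
    poly = poly.copy()
    while len(poly) < MIN_NODES:
        nxt = np.roll(poly, -1, axis=0)
        el = np.hypot(nxt[:, 0] - poly[:, 0], nxt[:, 1] - poly[:, 1])
        j = int(np.argmax(el))
        mid = 0.5 * (poly[j] + poly[(j + 1) % len(poly)])
        poly = np.insert(poly, j + 1, mid, axis=0)
    return poly


def sample_initial_cycles(n: int, rng: np.random.Generator,
                          low: float = 0.0, high: float = 4.0) -> np.ndarray:
    """Initial cell-cycle durations, i.i.d. uniform on [low, high] hours."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return rng.uniform(low, high, size=n)
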