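"""Geometric primitives: polyline cells and the rigid substrate.

Each cell's cortex in the apical-basal (XZ) cross-section is a closed
polyline of many nodes, stored counter-clockwise.  The substrate is a fixed
line of nodes on the X axis; its discretization matches the initial cell
node spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

MIN_NODES = 8


def polygon_signed_area(nodes: np.ndarray) -> float:
    """Signed shoelace area, positive for counter-clockwise node order."""
    x = nodes[:, 0]
    z = nodes[:, 1]
    return 0.5 * float(np.dot(x, np.roll(z, -1)) - np.dot(np.roll(x, -1), z))


def polygon_area(nodes: np.ndarray) -> float:
    """Unsigned enclosed area of a closed polyline."""
    return abs(polygon_signed_area(nodes))


def polygon_perimeter(nodes: np.ndarray) -> float:
    """Total length of the closed polyline, including the closing edge."""
    d = np.diff(np.vstack([nodes, nodes[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def polygon_centroid(nodes: np.ndarray) -> np.ndarray:
    """Vertex-average centroid (sufficient for left/right bookkeeping)."""
    return nodes.mean(axis=0)


def circularity(nodes: np.ndarray) -> float:
    """4*pi*A / P**2 of the outline; 1 for a circle."""
    p = polygon_perimeter(nodes)
    if p == 0:
        return 0.0
    return 4.0 * math.pi * polygon_area(nodes) / p**2


@dataclass
class Cell:
    """A cell cross-section: closed polyline plus per-cell mechanical state.

    Attributes
    ----------
    nodes : (N, 2) float array
        Node positions (x, z), counter-clockwise, N >= 8.
    preferred_area : float
        Current target area A0 (grows during the division program).
    node_ref_spacing : float
        Reference inter-node spacing fixed at construction; cortical
        remodeling keeps edges within [0.5, 2] times this value.
    cycle_length : float
        Cell-cycle duration in hours (math.inf for non-proliferative cells).
    age : float
        Time since birth, hours.
    gamma_cc : float or None
        Per-cell override of the cell-cell adhesion strength; None means
        "use the global parameter".  Set to 0.0 during the final hour of the
        cycle, when dividing cells cease cell-cell adhesion.
    """

    nodes: np.ndarray
    preferred_area: float
    node_ref_spacing: float
    cycle_length: float = math.inf
    age: float = 0.0
    dividing: bool = False
    gamma_cc: float | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 2:
            raise ValueError("nodes must be an (N, 2) array")
        if len(self.nodes) < MIN_NODES:
            raise ValueError(f"a cell needs at least {MIN_NODES} nodes")
        if not np.all(np.isfinite(self.nodes)):
            raise ValueError("node coordinates must be finite")
        # store counter-clockwise so the signed area is positive
        if polygon_signed_area(self.nodes) < 0:
            self.nodes = self.nodes[::-1].copy()

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def area(self) -> float:
        return polygon_area(self.nodes)

    def signed_area(self) -> float:
        return polygon_signed_area(self.nodes)

    def perimeter(self) -> float:
        return polygon_perimeter(self.nodes)

    def centroid(self) -> np.ndarray:
        return polygon_centroid(self.nodes)

    def aspect_ratio(self) -> float:
        """Bounding-box width / height."""
        w = float(self.nodes[:, 0].max() - self.nodes[:, 0].min())
        h = float(self.nodes[:, 1].max() - self.nodes[:, 1].min())
        return w / h if h > 0 else math.inf

    def copy(self) -> "Cell":
        c = Cell.__new__(Cell)
        c.nodes = self.nodes.copy()
        c.preferred_area = self.preferred_area
        c.node_ref_spacing = self.node_ref_spacing
        c.cycle_length = self.cycle_length
        c.age = self.age
        c.dividing = self.dividing
        c.gamma_cc = self.gamma_cc
        return c


@dataclass
class Substrate:
    """Fixed, rigid discretized line of nodes on z = 0."""

    nodes: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if not np.all(np.diff(self.nodes[:, 0]) > 0):
            raise ValueError("substrate nodes must be strictly increasing in x")
        self.nodes.setflags(write=False)

    @property
    def x(self) -> np.ndarray:
        return self.nodes[:, 0]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def x_min(self) -> float:
        return float(self.nodes[0, 0])

    @property
    def x_max(self) -> float:
        return float(self.nodes[-1, 0])

    @property
    def length(self) -> float:
        return self.x_max - self.x_min


def regular_polygon_radius(area: float, n_nodes: int) -> float:
    """Circumradius of the regular n-gon with the given enclosed area."""
    return math.sqrt(2.0 * area / (n_nodes * math.sin(2.0 * math.pi / n_nodes)))


def make_circular_cell(center: tuple[float, float], area: float,
                       n_nodes: int = 100, **cell_kwargs) -> Cell:
    """Build a regular-polygon cell whose *polygon* area equals ``area``.

    The reference node spacing is the polygon perimeter divided by the node
    count; cortical remodeling keeps the discretization near this value for
    the rest of the cell's life.
    """
    if area <= 0:
        raise ValueError("area must be positive")
    if n_nodes < MIN_NODES:
        raise ValueError(f"n_nodes must be at least {MIN_NODES}")
    r = regular_polygon_radius(area, n_nodes)
    theta = 2.0 * math.pi * np.arange(n_nodes) / n_nodes
    nodes = np.column_stack([center[0] + r * np.cos(theta),
                             center[1] + r * np.sin(theta)])
    spacing = 2.0 * n_nodes * r * math.sin(math.pi / n_nodes) / n_nodes
    return Cell(nodes=nodes, preferred_area=area,
                node_ref_spacing=spacing, **cell_kwargs)


def make_substrate(x_min: float, x_max: float, spacing: float) -> Substrate:
    """Uniformly spaced substrate nodes from x_min to x_max at z = 0.

    The last interval may be shorter than ``spacing`` so that the substrate
    ends exactly at ``x_max``.
    """
    if not x_max > x_min:
        raise ValueError("x_max must exceed x_min")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    n_full = int(math.floor((x_max - x_min) / spacing + 1e-12))
    xs = x_min + spacing * np.arange(n_full + 1)
    if xs[-1] < x_max - 1e-12 * max(1.0, abs(x_max)):
        xs = np.append(xs, x_max)
    nodes = np.column_stack([xs, np.zeros_like(xs)])
    return Substrate(nodes=nodes, spacing=spacing)


def standard_node_spacing(area: float = 1.0, n_nodes: int = 100) -> float:
    """Node spacing of the standard unit-area cell (sets substrate spacing)."""
    r = regular_polygon_radius(area, n_nodes)
    return 2.0 * r * math.sin(math.pi / n_nodes)
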