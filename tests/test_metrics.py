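import math

import numpy as np
import pytest

import epilayer.metrics as met
from epilayer import Cell
from epilayer.mechanics import BondSet


def make_bondset(n_cells, sub_pairs=(), cc_pairs=()):
    """Synthetic bond set: sub_pairs = [(cell, node, k)],
    cc_pairs = [(ci, ni, cj, nj, attractive)]."""
    sub = np.array(sub_pairs, dtype=np.intp).reshape(-1, 3)
    cc = np.array(cc_pairs, dtype=np.intp).reshape(-1, 5)
    return BondSet(
        sub_cell=sub[:, 0], sub_node=sub[:, 1], sub_k=sub[:, 2],
        cc_ci=cc[:, 0], cc_ni=cc[:, 1], cc_cj=cc[:, 2], cc_nj=cc[:, 3],
        cc_attractive=cc[:, 4].astype(bool),
        N_sub=np.bincount(sub[:, 0], minlength=n_cells),
        left_contact=np.zeros(n_cells, dtype=bool),
        right_contact=np.zeros(n_cells, dtype=bool))


def box_cell(x0, width=1.0, height=1.0, n_side=10):
    """Rectangular cell with n_side nodes per edge, counter-clockwise from
    the bottom-left corner."""
    b = [(x0 + t * width, 0.0) for t in np.linspace(0, 1, n_side, False)]
    r = [(x0 + width, t * height) for t in np.linspace(0, 1, n_side, False)]
    t_ = [(x0 + width - t * width, height)
          for t in np.linspace(0, 1, n_side, False)]
    l_ = [(x0, height - t * height) for t in np.linspace(0, 1, n_side, False)]
    return Cell(nodes=np.array(b + r + t_ + l_), preferred_area=width * height,
                node_ref_spacing=width / n_side)


class TestConnectionFractions:
    def test_counts_bonded_nodes(self):
        cell = box_cell(0.0, n_side=25)  # 100 nodes
        bonds = make_bondset(1, sub_pairs=[(0, j, j) for j in range(30)])
        f_cs, f_cc = met.connection_fractions(cell, 0, bonds)
        assert f_cs == pytest.approx(0.30)
        assert f_cc == 0.0

    def test_no_bonds(self):
        cell = box_cell(0.0)
        f_cs, f_cc = met.connection_fractions(cell, 0, make_bondset(1))
        assert (f_cs, f_cc) == (0.0, 0.0)

    def test_repulsive_bonds_not_counted(self):
        cell = box_cell(0.0)
        bonds = make_bondset(2, cc_pairs=[(0, 3, 1, 5, 0)])
        _, f_cc = met.connection_fractions(cell, 0, bonds)
        assert f_cc == 0.0


class TestLayerDensity:
    def test_anchored_conversion(self):
        # 4 cells spanning 4.78 model units (47.8 um) -> 7.0e3 cells/mm^2
        cells = [box_cell(1.195 * i, width=1.195) for i in range(4)]
        pairs = [(i, 0, 0) for i in range(4)]
        # outermost bonded nodes at x = 0 and x = 4.78
        cells[0].nodes[0] = [0.0, 0.0]
        cells[3].nodes[5] = [4.78, 0.0]
        bonds = make_bondset(4, sub_pairs=pairs + [(3, 5, 40)])
        linear, arb, per_mm2 = met.layer_density(cells, bonds)
        assert linear == pytest.approx(4 / 4.78)
        assert per_mm2 == pytest.approx(7002, rel=1e-3)
        assert arb == pytest.approx(7.0, rel=1e-3)

    def test_square_law(self):
        cells = [box_cell(float(i)) for i in range(2)]
        cells_b = [box_cell(float(i) / 2, width=0.5) for i in range(4)]
        span_pairs = [(0, 0, 0), (1, 5, 10)]
        cells[0].nodes[0] = [0.0, 0.0]
        cells[1].nodes[5] = [2.0, 0.0]
        cells_b[0].nodes[0] = [0.0, 0.0]
        cells_b[3].nodes[5] = [2.0, 0.0]
        _, arb2, _ = met.layer_density(cells, make_bondset(2, span_pairs))
        _, arb4, _ = met.layer_density(
            cells_b, make_bondset(4, [(0, 0, 0), (3, 5, 10)]))
        assert arb4 == pytest.approx(4 * arb2, rel=1e-12)

    def test_no_contact_flagged(self):
        with pytest.raises(ValueError):
            met.layer_density([box_cell(0.0)], make_bondset(1))


class TestApicalBasalRatio:
    def test_semicircular_cell(self):
        # flat bottom of radius r fully bonded, semicircular top free
        r = 1.0
        n_arc = 100
        theta = np.linspace(np.pi, 0.0, n_arc + 1)[:-1]
        arc = np.column_stack([r * np.cos(theta), r * np.sin(theta)])[::-1]
        bottom = np.column_stack([np.linspace(r, -r, 51)[1:-1],
                                  np.zeros(49)])[::-1]
        nodes = np.vstack([bottom, arc])
        cell = Cell(nodes=nodes, preferred_area=np.pi / 2,
                    node_ref_spacing=0.06)
        bottom_ids = [j for j in range(cell.n_nodes)
                      if cell.nodes[j, 1] == 0.0]
        bonds = make_bondset(1, sub_pairs=[(0, j, j) for j in bottom_ids])
        ratio = met.apical_basal_ratio(cell, 0, bonds)
        assert ratio == pytest.approx(np.pi / 2, rel=0.08)

    def test_fully_lateralized_rectangle(self):
        cell = box_cell(0.0, n_side=10)
        n = cell.n_nodes
        bottom = [j for j in range(n) if cell.nodes[j, 1] == 0.0]
        top = [j for j in range(n) if cell.nodes[j, 1] == 1.0]
        sides = [j for j in range(n) if j not in bottom + top]
        bonds = make_bondset(
            2, sub_pairs=[(0, j, j) for j in bottom],
            cc_pairs=[(0, j, 1, 0, 1) for j in sides])
        ratio = met.apical_basal_ratio(cell, 0, bonds)
        assert ratio == pytest.approx(1.0, rel=0.15)

    def test_no_substrate_contact_flagged(self):
        with pytest.raises(ValueError):
            met.apical_basal_ratio(box_cell(0.0), 0, make_bondset(1))


class TestClassification:
    @pytest.mark.parametrize("f_cc,label", [
        (0.05, met.IMMATURE), (0.15, met.INTERMEDIATE),
        (0.10, met.INTERMEDIATE)])
    def test_threshold(self, f_cc, label):
        assert met.classify_architecture(f_cc) == label

    def test_interior_cells_exclude_edges(self):
        cells = [box_cell(float(i)) for i in range(4)]
        interior = met.interior_cell_indices(cells)
        np.testing.assert_array_equal(interior, [1, 2])


class TestShapeIndex:
    def test_plateau_circularity_value(self):
        # the observed plateau circularity maps onto the jamming range of
        # 2D vertex models
        assert met.shape_index(0.84) == pytest.approx(3.868, abs=5e-4)

    def test_circle(self):
        assert met.shape_index(1.0) == pytest.approx(math.sqrt(4 * math.pi))

    def test_square_exact(self):
        assert met.shape_index(math.pi / 4) == pytest.approx(4.0, rel=1e-12)

    def test_vertex_model_consistency(self):
        circ = 4 * math.pi / 3.81 ** 2
        assert met.shape_index(circ) == pytest.approx(3.81, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_invalid_circularity(self, bad):
        with pytest.raises(ValueError):
            met.shape_index(bad)


class TestTransitionDensity:
    def test_interpolated_crossing(self):
        sweep = [(2, 0.04), (3, 0.09), (4, 0.13)]
        assert met.transition_density(sweep) == pytest.approx(3.25)

    def test_never_crossed(self):
        assert met.transition_density([(2, 0.01), (3, 0.05)]) is None

    def test_crossing_at_grid_point(self):
        sweep = [(2, 0.04), (3, 0.10), (4, 0.13)]
        assert met.transition_density(sweep) == pytest.approx(3.0)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            met.transition_density([(3, 0.04), (2, 0.05)])


class TestRatioTurning:
    def test_parabolic_peak(self):
        d = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
        r = 2.0 - (d - 6.0) ** 2 / 20.0
        assert met.ratio_turning_density(d, r) == pytest.approx(6.0, abs=0.3)

    def test_monotone_series_returns_endpoint(self):
        d = np.array([1.0, 2.0, 3.0])
        r = np.array([0.5, 0.8, 1.2])
        assert met.ratio_turning_density(d, r) == 3.0
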