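import math

import numpy as np
import pytest

import epilayer.mechanics as mech
from epilayer import (Cell, EffectiveParams, ModelParams, make_circular_cell,
                      make_substrate)
from epilayer.geometry import polygon_area, polygon_perimeter

from conftest import star_polygon


def make_cell(nodes, ref=0.1, **kw):
    return Cell(nodes=np.asarray(nodes, float), preferred_area=1.0,
                node_ref_spacing=ref, **kw)


def internal_energy(nodes, params, A0):
    A = polygon_area(nodes)
    L = polygon_perimeter(nodes)
    return 0.5 * params.k_A * (A - A0) ** 2 + 0.5 * params.k_L * L ** 2


def numeric_internal_force(cell, params, h=1e-6):
    """Central-difference -grad(E_int), the independent oracle."""
    F = np.zeros_like(cell.nodes)
    A0 = cell.preferred_area
    for j in range(len(cell.nodes)):
        for d in range(2):
            plus = cell.nodes.copy()
            minus = cell.nodes.copy()
            plus[j, d] += h
            minus[j, d] -= h
            F[j, d] = -(internal_energy(plus, params, A0)
                        - internal_energy(minus, params, A0)) / (2 * h)
    return F


class TestInternalForces:
    def test_forces_sum_to_zero(self, params, rng):
        for _ in range(5):
            cell = make_cell(star_polygon(rng))
            F = mech.internal_forces(cell, params)
            np.testing.assert_allclose(F.sum(axis=0), 0.0, atol=1e-10)

    def test_matches_finite_difference_gradient(self, params, rng):
        p = params.replace(k_L=0.02)  # make the perimeter term non-negligible
        for _ in range(10):
            cell = make_cell(star_polygon(rng))
            F = mech.internal_forces(cell, p)
            F_num = numeric_internal_force(cell, p)
            scale = max(1e-12, np.abs(F_num).max())
            assert np.abs(F - F_num).max() <= 1e-5 * scale

    def test_zero_at_energy_minimum(self):
        p = ModelParams(k_L=0.0)
        cell = make_circular_cell((0, 0), p.A0, 64)
        F = mech.internal_forces(cell, p)
        np.testing.assert_allclose(F, 0.0, atol=1e-9)

    def test_batched_path_matches_reference(self, params, rng):
        cells = [make_cell(star_polygon(rng, center=(3 * i, 0.8)), ref=0.05)
                 for i in range(3)]
        substrate = make_substrate(-3, 9, 0.05)
        eff = EffectiveParams.base(cells, params)
        bonds = mech.build_bond_set(cells, substrate, params, eff)
        ref_forces = mech.compute_forces(cells, substrate, params, bonds, eff)
        counts = np.array([c.n_nodes for c in cells])
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        pos = np.concatenate([c.nodes for c in cells])
        F = mech.assemble_forces_batch(cells, pos, starts, counts, substrate,
                                       params, bonds, eff, True)
        for i in range(len(cells)):
            np.testing.assert_allclose(
                F[starts[i]:starts[i] + counts[i]], ref_forces[i], atol=1e-13)


class TestSubstrateBonds:
    def test_in_and_out_of_range(self, params):
        sub = make_substrate(-1, 1, 0.5)
        cell = make_cell([[0, 0.05], [0.5, 0.4], [0.4, 0.9], [0.2, 1.2],
                          [0, 1.3], [-0.2, 1.2], [-0.4, 0.9], [-0.5, 0.4]])
        ci, ni, k = mech.match_substrate_bonds([cell], sub, params)
        assert len(ci) == 1
        np.testing.assert_allclose(cell.nodes[ni[0]], [0, 0.05])
        far = make_cell(np.array(cell.nodes) + [0, 0.10])
        ci, _, _ = mech.match_substrate_bonds([far], sub, params)
        assert len(ci) == 0

    def test_mutual_nearest_exclusivity(self, params):
        sub = make_substrate(-1, 1, 2.0)  # substrate nodes at -1 and 1 only
        cell = make_cell([[-1.0, 0.05], [-1.0, 0.08], [0, 0.5], [0.5, 0.8],
                          [0.5, 1.2], [0, 1.5], [-1.2, 1.2], [-1.4, 0.6]])
        ci, ni, k = mech.match_substrate_bonds([cell], sub, params)
        # two cell nodes compete for the substrate node at x=-1; closer wins
        assert len(ci) == 1
        np.testing.assert_allclose(cell.nodes[ni[0]], [-1.0, 0.05])
        # no substrate node appears twice; no cell node holds two bonds
        assert len(np.unique(k)) == len(k)
        assert len(np.unique(ni)) == len(ni)

    def test_force_values(self, params):
        # spring stretched to 0.1 (kept in range by a slightly larger d_cs)
        params = params.replace(d_cs=0.12)
        sub = make_substrate(-1, 1, 1.0)
        cell = make_cell([[0, 0.1], [0.4, 0.4], [0.5, 0.9], [0.3, 1.3],
                          [0, 1.4], [-0.3, 1.3], [-0.5, 0.9], [-0.4, 0.4]])
        eff = EffectiveParams.base([cell], params)
        bonds = mech.build_bond_set([cell], sub, params, eff)
        forces = [np.zeros_like(cell.nodes)]
        mech.substrate_adhesion_forces([cell], sub, bonds, eff.gamma_cs_eff,
                                       params, forces)
        mag = np.hypot(*forces[0][0])
        assert mag == pytest.approx(0.1 * (0.1 - 0.005), rel=1e-12)
        assert forces[0][0][1] < 0  # pulls toward the substrate
        assert np.all(forces[0][1:] == 0.0)

    def test_rest_length_gives_zero_force(self, params):
        sub = make_substrate(-1, 1, 1.0)
        cell = make_cell([[0, params.l_cs], [0.4, 0.4], [0.5, 0.9],
                          [0.3, 1.3], [0, 1.4], [-0.3, 1.3], [-0.5, 0.9],
                          [-0.4, 0.4]])
        eff = EffectiveParams.base([cell], params)
        bonds = mech.build_bond_set([cell], sub, params, eff)
        forces = [np.zeros_like(cell.nodes)]
        mech.substrate_adhesion_forces([cell], sub, bonds, eff.gamma_cs_eff,
                                       params, forces)
        np.testing.assert_allclose(forces[0], 0.0, atol=1e-15)


def two_cells_at_gap(gap):
    """Two octagonal cells whose facing nodes are ``gap`` apart."""
    theta = 2 * np.pi * np.arange(8) / 8
    poly = np.column_stack([0.5 * np.cos(theta), 0.5 * np.sin(theta)])
    left = make_cell(poly + [-0.5 - gap / 2, 0])
    right = make_cell(poly + [0.5 + gap / 2, 0])
    return [left, right]


class TestCellBonds:
    def test_attractive_and_repulsive_tagging(self, params):
        d_eff = np.full(2, params.d_cc)
        cells = two_cells_at_gap(0.1)
        ci, ni, cj, nj, dist, attr = mech.match_cell_bonds(
            cells, d_eff, params.l_cc)
        assert len(ci) >= 1 and np.all(attr)
        cells = two_cells_at_gap(0.003)
        *_, dist, attr = mech.match_cell_bonds(cells, d_eff, params.l_cc)
        assert np.any(~attr)

    def test_same_cell_never_bonded(self, params):
        cells = two_cells_at_gap(1.0)  # out of range entirely
        ci, *_ = mech.match_cell_bonds(cells, np.full(2, params.d_cc),
                                       params.l_cc)
        assert len(ci) == 0

    @pytest.mark.parametrize("gap,strength,expected", [
        (0.1, "gamma", 0.001 * 0.095),
        (0.005, "zero", 0.0),
        (0.003, "R", 0.05 * 0.002),
    ])
    def test_force_magnitudes(self, params, gap, strength, expected):
        cells = two_cells_at_gap(gap)
        sub = make_substrate(-5, 5, 1.0)
        eff = EffectiveParams.base(cells, params)
        bonds = mech.build_bond_set(cells, sub, params, eff)
        forces = [np.zeros_like(c.nodes) for c in cells]
        mech.cell_adhesion_forces(cells, bonds, eff.gamma_cc_eff, params,
                                  forces)
        # facing nodes: index 0 of the left cell (angle 0) faces index 4
        # (angle pi) of the right cell
        mag = np.hypot(*forces[0][0])
        assert mag == pytest.approx(expected, rel=1e-9, abs=1e-15)
        # equal and opposite on the two endpoints
        np.testing.assert_allclose(forces[0][0], -forces[1][4], atol=1e-15)

    def test_pairwise_forces_cancel(self, params, rng):
        cells = [make_cell(star_polygon(rng, center=(1.1 * i, 0)), ref=0.05)
                 for i in range(3)]
        sub = make_substrate(-5, 5, 1.0)
        eff = EffectiveParams.base(cells, params)
        bonds = mech.build_bond_set(cells, sub, params, eff)
        forces = [np.zeros_like(c.nodes) for c in cells]
        mech.cell_adhesion_forces(cells, bonds, eff.gamma_cc_eff, params,
                                  forces)
        total = sum(f.sum(axis=0) for f in forces)
        np.testing.assert_allclose(total, 0.0, atol=1e-12)


class TestGravity:
    def _forces(self, cells, bonds, params):
        forces = [np.zeros_like(c.nodes) for c in cells]
        mech.gravity_forces(cells, bonds, params, forces)
        return forces

    def test_isolated_floating_cell(self, params):
        cell = make_circular_cell((0, 5), 1.0, 16)
        sub = make_substrate(-1, 1, 0.5)
        eff = EffectiveParams.base([cell], params)
        bonds = mech.build_bond_set([cell], sub, params, eff)
        (F,) = self._forces([cell], bonds, params)
        np.testing.assert_allclose(F[:, 1], -params.C_G)
        np.testing.assert_allclose(F[:, 0], 0.0)

    def test_substrate_bonded_cell_excluded(self, params):
        cell = make_circular_cell((0, 0.60), 1.0, 64)  # bottom within d_cs
        sub = make_substrate(-2, 2, 0.05)
        eff = EffectiveParams.base([cell], params)
        bonds = mech.build_bond_set([cell], sub, params, eff)
        assert bonds.n_substrate_bonds > 0
        (F,) = self._forces([cell], bonds, params)
        np.testing.assert_allclose(F, 0.0)

    def test_path_through_neighbor(self, params):
        grounded = make_circular_cell((0, 0.60), 1.0, 64)
        floater = make_circular_cell((1.25, 0.75), 1.0, 64)  # touches neighbor
        lone = make_circular_cell((6.0, 3.0), 1.0, 64)
        sub = make_substrate(-2, 8, 0.05)
        cells = [grounded, floater, lone]
        eff = EffectiveParams.base(cells, params)
        bonds = mech.build_bond_set(cells, sub, params, eff)
        assert bonds.n_cell_bonds > 0
        F = self._forces(cells, bonds, params)
        np.testing.assert_allclose(F[1], 0.0)          # path to substrate
        np.testing.assert_allclose(F[2][:, 1], -params.C_G)  # truly floating


class TestFeedback:
    def test_no_contact_keeps_base_values(self, params):
        cells = [make_circular_cell((0, 0), 1.0, 16)]
        eff = mech.effective_adhesion_params(
            cells, np.array([False]), np.array([10]), params)
        assert eff.gamma_cc_eff[0] == params.gamma_cc
        assert eff.gamma_cs_eff[0] == params.gamma_cs
        assert eff.d_cc_eff[0] == params.d_cc

    def test_contact_boosts(self, params):
        cells = [make_circular_cell((0, 0), 1.0, 16)]
        eff = mech.effective_adhesion_params(
            cells, np.array([True]), np.array([10]), params)
        assert eff.gamma_cc_eff[0] == pytest.approx(1.3 * params.gamma_cc)
        assert eff.gamma_cs_eff[0] == pytest.approx(1.5 * params.gamma_cs)
        assert eff.d_cc_eff[0] == pytest.approx(0.192)

    def test_contact_with_no_substrate_bonds(self, params):
        cells = [make_circular_cell((0, 0), 1.0, 16)]
        eff = mech.effective_adhesion_params(
            cells, np.array([True]), np.array([0]), params)
        assert eff.gamma_cc_eff[0] == params.gamma_cc
        assert eff.gamma_cs_eff[0] == pytest.approx(1.5 * params.gamma_cs)

    def test_division_override_respected(self, params):
        cell = make_circular_cell((0, 0), 1.0, 16)
        cell.gamma_cc = 0.0
        eff = mech.effective_adhesion_params(
            [cell], np.array([True]), np.array([5]), params)
        assert eff.gamma_cc_eff[0] == 0.0


class TestSpreading:
    def test_scale_models(self, params):
        assert mech.spreading_scale("constant", 0.02, params) == 0.008
        assert mech.spreading_scale("linear", 0.05, params) == pytest.approx(
            0.5 * 0.008)
        assert mech.spreading_scale("nonlinear", 0.02, params) == (
            pytest.approx(0.2 ** 0.2 * 0.008))
        with pytest.raises(ValueError):
            mech.spreading_scale("linear", 0.05,
                                 params.replace(gamma_cs_ref=0.0))

    def test_below_activation_no_force(self, params, unit_cell):
        mask = np.zeros(100, dtype=bool)
        mask[:5] = True  # 5% < 10% activation
        F = np.zeros_like(unit_cell.nodes)
        mech.spreading_forces(unit_cell, mask, False, False, params.C_s,
                              params, F)
        assert np.all(F == 0.0)

    def test_two_flank_nodes_mirror_symmetric(self, params, unit_cell):
        # nodes 0..99 counter-clockwise from (r, 0); bottom arc is the
        # second half of the index range
        mask = np.zeros(100, dtype=bool)
        mask[55:85] = True  # 30 bonded nodes on the lower arc
        F = np.zeros_like(unit_cell.nodes)
        mech.spreading_forces(unit_cell, mask, False, False, params.C_s,
                              params, F)
        loaded = np.nonzero(np.any(F != 0, axis=1))[0]
        assert len(loaded) == 2
        fl, fr = sorted(loaded, key=lambda j: unit_cell.nodes[j, 0])
        np.testing.assert_allclose(F[fl], params.C_s * np.array(
            [-math.sqrt(0.5), -math.sqrt(0.5)]), atol=1e-12)
        np.testing.assert_allclose(F[fr], params.C_s * np.array(
            [math.sqrt(0.5), -math.sqrt(0.5)]), atol=1e-12)

    def test_contact_inhibition_per_side(self, params, unit_cell):
        mask = np.zeros(100, dtype=bool)
        mask[55:85] = True
        F = np.zeros_like(unit_cell.nodes)
        mech.spreading_forces(unit_cell, mask, True, False, params.C_s,
                              params, F)
        loaded = np.nonzero(np.any(F != 0, axis=1))[0]
        assert len(loaded) == 1
        assert F[loaded[0], 0] > 0  # only the right flank is pushed
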