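"""Force contributions and adhesion-bond bookkeeping.

The net force on node j of cell i is the sum of five terms:

    F = F_internal + F_cs + F_cc + F_spread + F_gravity

* F_internal is the negative gradient of the internal energy
  E_int = 1/2 k_A (A - A0)^2 + 1/2 k_L L^2 (area elasticity plus cortical
  perimeter minimization).
* F_cs / F_cc are linear springs between nearby cell-substrate / cell-cell
  node pairs; springs are stateless and recomputed every step, so "breaking"
  is equivalent to leaving the interaction range.
* F_spread is an active lamellipodial force on the nodes flanking the
  outermost substrate connections, pointing 45 degrees outward and below
  horizontal, subject to contact inhibition per cell side.
* F_gravity is a small constant downward force on cells without a contact
  path to the substrate.

A feedback mechanism models the crosstalk between the two adhesion systems:
once a cell has a cell-cell contact, its gamma_cc is boosted by its current
number of substrate bonds, its gamma_cs by a factor 1.5, and its cell-cell
interaction range d_cc by a factor 1.2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import Cell, Substrate
from .params import ModelParams

__all__ = [
    "BondSet", "EffectiveParams", "internal_forces",
    "match_substrate_bonds", "substrate_adhesion_forces",
    "match_cell_bonds", "cell_adhesion_forces", "contact_flags",
    "gravity_forces", "effective_adhesion_params",
    "spreading_scale", "spreading_forces", "compute_forces",
]


@dataclass
class BondSet:
    """Current adhesion springs, as index arrays.

    Substrate bonds pair (cell, node) with a substrate node under mutual
    nearest-neighbor exclusivity.  Cell-cell bonds pair nodes of distinct
    cells; every qualifying pair is kept (the force law is a double sum).
    """

    # cell-substrate bonds
    sub_cell: np.ndarray   # (n_sb,) int, cell index
    sub_node: np.ndarray   # (n_sb,) int, node index within the cell
    sub_k: np.ndarray      # (n_sb,) int, substrate node index
    # cell-cell bonds (ci < cj by construction)
    cc_ci: np.ndarray
    cc_ni: np.ndarray
    cc_cj: np.ndarray
    cc_nj: np.ndarray
    cc_attractive: np.ndarray  # (n_cc,) bool; False = repulsive (d < l_cc)
    # per-cell summaries
    N_sub: np.ndarray          # substrate-bond count per cell
    left_contact: np.ndarray   # per-cell bool: attractive contact on -x side
    right_contact: np.ndarray  # per-cell bool: attractive contact on +x side

    @property
    def n_substrate_bonds(self) -> int:
        return len(self.sub_cell)

    @property
    def n_cell_bonds(self) -> int:
        return len(self.cc_ci)

    def has_cc_contact(self) -> np.ndarray:
        """Per-cell flag: holds at least one attractive cell-cell bond."""
        n = len(self.N_sub)
        flag = np.zeros(n, dtype=bool)
        if self.n_cell_bonds:
            att = self.cc_attractive
            flag[np.unique(self.cc_ci[att])] = True
            flag[np.unique(self.cc_cj[att])] = True
        return flag

    def substrate_bonded_mask(self, cell_index: int, n_nodes: int) -> np.ndarray:
        mask = np.zeros(n_nodes, dtype=bool)
        sel = self.sub_cell == cell_index
        mask[self.sub_node[sel]] = True
        return mask

    def cc_bonded_mask(self, cell_index: int, n_nodes: int,
                       attractive_only: bool = True) -> np.ndarray:
        mask = np.zeros(n_nodes, dtype=bool)
        if self.n_cell_bonds == 0:
            return mask
        keep = self.cc_attractive if attractive_only else np.ones(
            self.n_cell_bonds, dtype=bool)
        sel = keep & (self.cc_ci == cell_index)
        mask[self.cc_ni[sel]] = True
        sel = keep & (self.cc_cj == cell_index)
        mask[self.cc_nj[sel]] = True
        return mask


@dataclass
class EffectiveParams:
    """Per-cell adhesion parameters after the contact feedback."""

    gamma_cc_eff: np.ndarray
    gamma_cs_eff: np.ndarray
    d_cc_eff: np.ndarray

    @classmethod
    def base(cls, cells: list[Cell], params: ModelParams) -> "EffectiveParams":
        n = len(cells)
        gcc = np.array([params.gamma_cc if c.gamma_cc is None else c.gamma_cc
                        for c in cells])
        return cls(gamma_cc_eff=gcc,
                   gamma_cs_eff=np.full(n, params.gamma_cs),
                   d_cc_eff=np.full(n, params.d_cc))


# ---------------------------------------------------------------------------
# internal (area + perimeter) forces

def _shift_m1(a: np.ndarray) -> np.ndarray:
    """a rolled by -1 (cyclic successor), without np.roll overhead."""
    out = np.empty_like(a)
    out[:-1] = a[1:]
    out[-1] = a[0]
    return out


def _shift_p1(a: np.ndarray) -> np.ndarray:
    """a rolled by +1 (cyclic predecessor)."""
    out = np.empty_like(a)
    out[1:] = a[:-1]
    out[0] = a[-1]
    return out


def internal_forces(cell: Cell, params: ModelParams,
                    preferred_area: float | None = None) -> np.ndarray:
    """Negative gradient of E_int = 1/2 k_A (A-A0)^2 + 1/2 k_L L^2.

    Area term on node j: -k_A (A - A0) * sign(S) * 1/2 (z_{j+1}-z_{j-1},
    x_{j-1}-x_{j+1}); perimeter term: k_L * L * (u_j - u_{j-1}) where u_j is
    the unit tangent of edge j -> j+1.  Degenerate (zero-length) edges
    contribute a zero tangent.
    """
    nodes = cell.nodes
    A0 = cell.preferred_area if preferred_area is None else preferred_area
    x = nodes[:, 0]
    z = nodes[:, 1]
    xp = _shift_m1(x)
    zp = _shift_m1(z)
    xm = _shift_p1(x)
    zm = _shift_p1(z)

    S = 0.5 * float(np.dot(x, zp) - np.dot(xp, z))
    A = abs(S)
    sgn = 1.0 if S >= 0 else -1.0

    ex = xp - x
    ez = zp - z
    el = np.sqrt(ex * ex + ez * ez)
    L = float(el.sum())
    if not el.all():
        warnings.warn("degenerate zero-length edge; tangent treated as zero",
                      RuntimeWarning, stacklevel=2)
        inv = np.where(el > 0.0, 1.0 / np.where(el > 0.0, el, 1.0), 0.0)
    else:
        inv = 1.0 / el
    ux = ex * inv
    uz = ez * inv

    coefA = -params.k_A * (A - A0) * sgn * 0.5
    F = np.empty_like(nodes)
    F[:, 0] = coefA * (zp - zm) + params.k_L * L * (ux - _shift_p1(ux))
    F[:, 1] = coefA * (xm - xp) + params.k_L * L * (uz - _shift_p1(uz))
    return F


# ---------------------------------------------------------------------------
# bond matching

def match_substrate_bonds(cells: list[Cell], substrate: Substrate,
                          params: ModelParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mutual-nearest substrate springs within range d_cs.

    A bond (cell node j, substrate node k) exists iff |p_j - s_k| < d_cs,
    k is j's nearest substrate node and j is k's nearest cell node.
    Returns (cell_idx, node_idx, substrate_idx) arrays.
    """
    xs = substrate.x
    counts = [c.n_nodes for c in cells]
    if not counts:
        e = np.empty(0, dtype=np.intp)
        return e, e.copy(), e.copy()
    px = np.concatenate([c.nodes[:, 0] for c in cells])
    pz = np.concatenate([c.nodes[:, 1] for c in cells])

    # nearest substrate node: all substrate z are 0, so nearest in |x| wins
    hi = np.searchsorted(xs, px)
    hi = np.clip(hi, 1, len(xs) - 1)
    lo = hi - 1
    pick_hi = (xs[hi] - px) < (px - xs[lo])
    k = np.where(pick_hi, hi, lo)
    dist = np.hypot(px - xs[k], pz)

    cand = np.nonzero(dist < params.d_cs)[0]
    if cand.size == 0:
        e = np.empty(0, dtype=np.intp)
        return e, e.copy(), e.copy()
    ck = k[cand]
    cd = dist[cand]
    # per substrate node keep only the closest cell node (stable tie-break)
    order = np.lexsort((cand, cd, ck))
    ck_sorted = ck[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = ck_sorted[1:] != ck_sorted[:-1]
    winners = cand[order[first]]
    wk = k[winners]

    offsets = np.cumsum([0] + counts)
    cell_idx = np.searchsorted(offsets, winners, side="right") - 1
    node_idx = winners - offsets[cell_idx]
    srt = np.lexsort((node_idx, cell_idx))
    return (cell_idx[srt].astype(np.intp), node_idx[srt].astype(np.intp),
            wk[srt].astype(np.intp))


def match_cell_bonds(cells: list[Cell], d_cc_eff: np.ndarray,
                     l_cc: float) -> tuple[np.ndarray, ...]:
    """All inter-cell node pairs within the (symmetric) interaction range.

    The range for a pair of cells is max(d_cc_eff_i, d_cc_eff_j) so bond
    existence is symmetric.  No exclusivity: the force law is a double sum
    over all qualifying pairs.  Returns (ci, ni, cj, nj, dist, attractive).
    """
    CI, NI, CJ, NJ, D = [], [], [], [], []
    n = len(cells)
    for i in range(n):
        a = cells[i].nodes
        for j in range(i + 1, n):
            b = cells[j].nodes
            rng = max(d_cc_eff[i], d_cc_eff[j])
            # bounding-box prune
            if (a[:, 0].min() - rng > b[:, 0].max()
                    or b[:, 0].min() - rng > a[:, 0].max()
                    or a[:, 1].min() - rng > b[:, 1].max()
                    or b[:, 1].min() - rng > a[:, 1].max()):
                continue
            dx = a[:, 0, None] - b[None, :, 0]
            dz = a[:, 1, None] - b[None, :, 1]
            d2 = dx * dx + dz * dz
            ii, jj = np.nonzero(d2 < rng * rng)
            if ii.size == 0:
                continue
            CI.append(np.full(ii.size, i, dtype=np.intp))
            NI.append(ii)
            CJ.append(np.full(ii.size, j, dtype=np.intp))
            NJ.append(jj)
            D.append(np.sqrt(d2[ii, jj]))
    if not CI:
        e = np.empty(0, dtype=np.intp)
        return e, e.copy(), e.copy(), e.copy(), np.empty(0), np.empty(0, bool)
    ci = np.concatenate(CI)
    ni = np.concatenate(NI)
    cj = np.concatenate(CJ)
    nj = np.concatenate(NJ)
    dist = np.concatenate(D)
    return ci, ni, cj, nj, dist, dist > l_cc


def contact_flags(cells: list[Cell], ci, ni, cj, nj,
                  attractive) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell left/right contact indicators from attractive bonds.

    A bond whose partner cell's centroid lies at lower x than this cell's
    centroid sets the LEFT flag, otherwise the RIGHT flag.
    """
    n = len(cells)
    left = np.zeros(n, dtype=bool)
    right = np.zeros(n, dtype=bool)
    if len(ci) == 0:
        return left, right
    cx = np.array([c.centroid()[0] for c in cells])
    for a, b in zip(ci[attractive], cj[attractive]):
        if cx[b] < cx[a]:
            left[a] = True
            right[b] = True
        else:
            right[a] = True
            left[b] = True
    return left, right


def build_bond_set(cells: list[Cell], substrate: Substrate,
                   params: ModelParams,
                   effective: EffectiveParams) -> BondSet:
    """Recompute all bonds from current positions (stateless springs)."""
    sc, sn, sk = match_substrate_bonds(cells, substrate, params)
    ci, ni, cj, nj, dist, attractive = match_cell_bonds(
        cells, effective.d_cc_eff, params.l_cc)
    n = len(cells)
    N_sub = np.bincount(sc, minlength=n).astype(np.intp)
    left, right = contact_flags(cells, ci, ni, cj, nj, attractive)
    return BondSet(sub_cell=sc, sub_node=sn, sub_k=sk,
                   cc_ci=ci, cc_ni=ni, cc_cj=cj, cc_nj=nj,
                   cc_attractive=attractive,
                   N_sub=N_sub, left_contact=left, right_contact=right)


# ---------------------------------------------------------------------------
# forces from bonds

def substrate_adhesion_forces(cells: list[Cell], substrate: Substrate,
                              bonds: BondSet, gamma_cs_eff: np.ndarray,
                              params: ModelParams,
                              forces: list[np.ndarray]) -> None:
    """Accumulate F_cs = -gamma_cs_eff (|p-s| - l_cs) (p-s)/|p-s| per bond."""
    if bonds.n_substrate_bonds == 0:
        return
    for c in np.unique(bonds.sub_cell):
        sel = bonds.sub_cell == c
        nidx = bonds.sub_node[sel]
        p = cells[c].nodes[nidx]
        s = substrate.nodes[bonds.sub_k[sel]]
        delta = p - s
        d = np.hypot(delta[:, 0], delta[:, 1])
        if np.any(d == 0.0):
            warnings.warn("cell node coincides with substrate node; "
                          "bond force set to zero", RuntimeWarning,
                          stacklevel=2)
        inv = np.where(d > 0.0, 1.0 / np.where(d > 0.0, d, 1.0), 0.0)
        coef = -gamma_cs_eff[c] * (d - params.l_cs) * inv
        np.add.at(forces[c], nidx, coef[:, None] * delta)


def cell_adhesion_forces(cells: list[Cell], bonds: BondSet,
                         gamma_cc_eff: np.ndarray, params: ModelParams,
                         forces: list[np.ndarray]) -> None:
    """Accumulate the attractive/repulsive cell-cell spring forces.

    Attractive branch (l_cc < d < d_cc): strength min(gamma_i, gamma_j), so
    pair forces stay equal and opposite even when the two cells' effective
    adhesions differ (e.g. one is ceasing adhesion before division).
    Repulsive branch (d < l_cc): fixed strength R_cc, independent of
    adhesion.
    """
    if bonds.n_cell_bonds == 0:
        return
    ci, ni, cj, nj = bonds.cc_ci, bonds.cc_ni, bonds.cc_cj, bonds.cc_nj
    pi = np.empty((len(ci), 2))
    pj = np.empty_like(pi)
    for c in np.unique(ci):
        sel = ci == c
        pi[sel] = cells[c].nodes[ni[sel]]
    for c in np.unique(cj):
        sel = cj == c
        pj[sel] = cells[c].nodes[nj[sel]]
    delta = pi - pj
    d = np.hypot(delta[:, 0], delta[:, 1])
    if np.any(d == 0.0):
        warnings.warn("coincident nodes of different cells; bond force "
                      "set to zero", RuntimeWarning, stacklevel=2)
    inv = np.where(d > 0.0, 1.0 / np.where(d > 0.0, d, 1.0), 0.0)
    g = np.where(bonds.cc_attractive,
                 np.minimum(gamma_cc_eff[ci], gamma_cc_eff[cj]),
                 params.R_cc)
    coef = -g * (d - params.l_cc) * inv
    fvec = coef[:, None] * delta
    for c in np.unique(ci):
        sel = ci == c
        np.add.at(forces[c], ni[sel], fvec[sel])
    for c in np.unique(cj):
        sel = cj == c
        np.add.at(forces[c], nj[sel], -fvec[sel])


def gravity_forces(cells: list[Cell], bonds: BondSet, params: ModelParams,
                   forces: list[np.ndarray]) -> None:
    """Constant downward force on every node of cells without a contact
    path (through any bonds, attractive or repulsive) to the substrate."""
    n = len(cells)
    grounded = _grounded_cells(n, bonds)
    for c in range(n):
        if not grounded[c]:
            forces[c][:, 1] -= params.C_G


def effective_adhesion_params(cells: list[Cell], has_cc_contact: np.ndarray,
                              N_sub: np.ndarray,
                              params: ModelParams) -> EffectiveParams:
    """Apply the adhesion-crosstalk feedback per cell.

    With cell-cell contact: gamma_cc -> gamma_cc (1 + 0.03 N_sub),
    gamma_cs -> 1.5 gamma_cs, d_cc -> 1.2 d_cc.  Without contact the base
    values apply.  Per-cell gamma_cc overrides (division program) are
    respected before the boost.
    """
    eff = EffectiveParams.base(cells, params)
    boost = has_cc_contact
    eff.gamma_cc_eff = np.where(
        boost, eff.gamma_cc_eff * (1.0 + params.feedback_cc_per_bond * N_sub),
        eff.gamma_cc_eff)
    eff.gamma_cs_eff = np.where(
        boost, params.feedback_cs_factor * eff.gamma_cs_eff,
        eff.gamma_cs_eff)
    eff.d_cc_eff = np.where(
        boost, params.feedback_dcc_factor * eff.d_cc_eff, eff.d_cc_eff)
    return eff


# ---------------------------------------------------------------------------
# active spreading

def spreading_scale(mode: str, gamma_cs: float, params: ModelParams) -> float:
    """Spreading-force magnitude under the chosen adhesion-scaling model.

    constant: C_s; linear: C_s * (gamma_cs / gamma_cs0);
    nonlinear: C_s * (gamma_cs / gamma_cs0) ** 0.2.
    """
    if gamma_cs < 0:
        raise ValueError("gamma_cs must be >= 0")
    if mode == "constant":
        return params.C_s
    if params.gamma_cs_ref <= 0:
        raise ValueError("gamma_cs_ref must be positive for scaled spreading")
    ratio = gamma_cs / params.gamma_cs_ref
    if mode == "linear":
        return params.C_s * ratio
    if mode == "nonlinear":
        return params.C_s * ratio ** params.spreading_exponent
    raise ValueError(f"unknown spreading mode {mode!r}")


_SQ2 = np.sqrt(0.5)


def spreading_forces(cell: Cell, sub_mask: np.ndarray, left_contact: bool,
                     right_contact: bool, scale: float,
                     params: ModelParams, force: np.ndarray) -> None:
    """Accumulate the active spreading force for one cell.

    Active only once the fraction of substrate-bonded nodes reaches the
    activation fraction.  The polyline neighbors of the leftmost and
    rightmost bonded nodes each receive scale * (+-sqrt2/2, -sqrt2/2),
    unless that side of the cell touches a neighbor (contact inhibition of
    spreading, per side).
    """
    n = cell.n_nodes
    nb = int(sub_mask.sum())
    if nb == 0 or nb < params.activation_fraction * n:
        return
    idx = np.nonzero(sub_mask)[0]
    xs = cell.nodes[idx, 0]
    for side in ("left", "right"):
        if side == "left":
            if left_contact:
                continue
            anchor = idx[np.argmin(xs)]
            direction = np.array([-_SQ2, -_SQ2])
        else:
            if right_contact:
                continue
            anchor = idx[np.argmax(xs)]
            direction = np.array([_SQ2, -_SQ2])
        nbrs = [(anchor - 1) % n, (anchor + 1) % n]
        free = [j for j in nbrs if not sub_mask[j]]
        if not free:
            continue  # fully bonded cortex, nothing outside the run
        if len(free) == 2:
            # pick the flank node outward of the bonded run on this side
            if side == "left":
                flank = min(free, key=lambda j: cell.nodes[j, 0])
            else:
                flank = max(free, key=lambda j: cell.nodes[j, 0])
        else:
            flank = free[0]
        force[flank] += scale * direction


# ---------------------------------------------------------------------------
# batched force assembly over concatenated node arrays
#
# The engine's hot loop operates on all cells' nodes concatenated into one
# (M, 2) array, with per-cell segment sums done via np.add.reduceat.  The
# per-cell functions above are the reference implementation; the batched
# path is checked against them in the test suite.

def internal_forces_batch(pos: np.ndarray, starts: np.ndarray,
                          counts: np.ndarray, preferred_areas: np.ndarray,
                          params: ModelParams) -> np.ndarray:
    """Internal forces for all cells at once; ``starts`` indexes segment
    beginnings in the concatenated position array."""
    x = pos[:, 0]
    z = pos[:, 1]
    M = len(pos)
    succ = np.arange(1, M + 1)
    ends = starts + counts
    succ[ends - 1] = starts
    prd = np.arange(-1, M - 1)
    prd[starts] = ends - 1

    xp = x[succ]
    zp = z[succ]
    term = x * zp - xp * z
    S = 0.5 * np.add.reduceat(term, starts)
    A = np.abs(S)
    sgn = np.where(S >= 0, 1.0, -1.0)

    ex = xp - x
    ez = zp - z
    el = np.sqrt(ex * ex + ez * ez)
    L = np.add.reduceat(el, starts)
    if not el.all():
        warnings.warn("degenerate zero-length edge; tangent treated as zero",
                      RuntimeWarning, stacklevel=2)
        inv = np.where(el > 0.0, 1.0 / np.where(el > 0.0, el, 1.0), 0.0)
    else:
        inv = 1.0 / el
    ux = ex * inv
    uz = ez * inv

    coefA = np.repeat(-params.k_A * (A - preferred_areas) * sgn * 0.5, counts)
    kLL = np.repeat(params.k_L * L, counts)
    F = np.empty_like(pos)
    F[:, 0] = coefA * (zp - z[prd]) + kLL * (ux - ux[prd])
    F[:, 1] = coefA * (x[prd] - xp) + kLL * (uz - uz[prd])
    return F


def assemble_forces_batch(cells: list[Cell], pos: np.ndarray,
                          starts: np.ndarray, counts: np.ndarray,
                          substrate: Substrate, params: ModelParams,
                          bonds: BondSet, effective: EffectiveParams,
                          spreading_enabled: bool) -> np.ndarray:
    """Sum all five force terms on the concatenated node array."""
    A0s = np.array([c.preferred_area for c in cells])
    F = internal_forces_batch(pos, starts, counts, A0s, params)

    # substrate springs
    if bonds.n_substrate_bonds:
        g = starts[bonds.sub_cell] + bonds.sub_node
        delta = pos[g] - substrate.nodes[bonds.sub_k]
        d = np.sqrt(delta[:, 0] ** 2 + delta[:, 1] ** 2)
        inv = np.where(d > 0.0, 1.0 / np.where(d > 0.0, d, 1.0), 0.0)
        coef = -effective.gamma_cs_eff[bonds.sub_cell] * (d - params.l_cs) * inv
        np.add.at(F, g, coef[:, None] * delta)

    # cell-cell springs
    if bonds.n_cell_bonds:
        gi = starts[bonds.cc_ci] + bonds.cc_ni
        gj = starts[bonds.cc_cj] + bonds.cc_nj
        delta = pos[gi] - pos[gj]
        d = np.sqrt(delta[:, 0] ** 2 + delta[:, 1] ** 2)
        inv = np.where(d > 0.0, 1.0 / np.where(d > 0.0, d, 1.0), 0.0)
        strength = np.where(
            bonds.cc_attractive,
            np.minimum(effective.gamma_cc_eff[bonds.cc_ci],
                       effective.gamma_cc_eff[bonds.cc_cj]),
            params.R_cc)
        fvec = (-strength * (d - params.l_cc) * inv)[:, None] * delta
        np.add.at(F, gi, fvec)
        np.add.at(F, gj, -fvec)

    # gravity on cells without a contact path to the substrate
    grounded = _grounded_cells(len(cells), bonds)
    for i in range(len(cells)):
        if not grounded[i]:
            F[starts[i]:starts[i] + counts[i], 1] -= params.C_G

    # active spreading
    if spreading_enabled:
        scale = spreading_scale(params.spreading_mode, params.gamma_cs, params)
        if scale != 0.0:
            for i, c in enumerate(cells):
                mask = bonds.substrate_bonded_mask(i, counts[i])
                spreading_forces(c, mask, bool(bonds.left_contact[i]),
                                 bool(bonds.right_contact[i]), scale, params,
                                 F[starts[i]:starts[i] + counts[i]])
    return F


def _grounded_cells(n: int, bonds: BondSet) -> np.ndarray:
    grounded = np.zeros(n, dtype=bool)
    grounded[np.unique(bonds.sub_cell)] = True
    if bonds.n_cell_bonds and not grounded.all():
        edges = set(zip(bonds.cc_ci.tolist(), bonds.cc_cj.tolist()))
        changed = True
        while changed:
            changed = False
            for a, b in edges:
                if grounded[a] != grounded[b]:
                    grounded[a] = grounded[b] = True
                    changed = True
    return grounded


# ---------------------------------------------------------------------------
# full force assembly (reference per-cell path, used by tests)

def compute_forces(cells: list[Cell], substrate: Substrate,
                   params: ModelParams, bonds: BondSet,
                   effective: EffectiveParams,
                   spreading_enabled: bool = True) -> list[np.ndarray]:
    """Sum the five force terms per node for every cell."""
    forces = [np.zeros_like(c.nodes) for c in cells]
    for i, c in enumerate(cells):
        forces[i] += internal_forces(c, params)
    substrate_adhesion_forces(cells, substrate, bonds,
                              effective.gamma_cs_eff, params, forces)
    cell_adhesion_forces(cells, bonds, effective.gamma_cc_eff, params, forces)
    gravity_forces(cells, bonds, params, forces)
    if spreading_enabled:
        scale = spreading_scale(params.spreading_mode, params.gamma_cs, params)
        for i, c in enumerate(cells):
            mask = bonds.substrate_bonded_mask(i, c.n_nodes)
            spreading_forces(c, mask, bool(bonds.left_contact[i]),
                             bool(bonds.right_contact[i]), scale, params,
                             forces[i])
    return forces
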