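# Methods

## Model

`epilayer` simulates the apical-basal (XZ) cross-section of cultured
epithelial cells as deformable polylines: each cell cortex is a closed,
counter-clockwise chain of ~100 nodes, and the substrate is a fixed, rigid
line of nodes on the X axis whose spacing equals the initial cell node
spacing.  Node positions evolve by overdamped dynamics, F = beta v,
integrated with an explicit Euler step

    p  <-  p + dt * F / beta,        dt = 1,  beta = 1,

with 750 timesteps corresponding to one hour in culture.  The net force on
a node is the sum of five terms.

**Internal regulation of size and shape.**  Each cell penalizes deviation
of its enclosed area A from a preferred value A0 and minimizes its
cortical perimeter L through the energy

    E_int = 1/2 k_A (A - A0)^2 + 1/2 k_L L^2,

whose negative nodal gradient combines a pressure-like area term
(proportional to the rotated difference of the node's neighbors, with the
sign of the shoelace sum) and a cortical-tension term k_L L (u_j -
u_{j-1}) built from unit edge tangents.  In isolation the minimizer is a
circle of area A* = A0 - 2 pi k_L / k_A (0.996858 in model units), which
the integrator reproduces to ~5e-4 relative; this closed form anchors the
analytic regression test.

**Adhesion springs.**  Cell-substrate and cell-cell adhesions are linear
springs between node pairs that are within an interaction distance (d_cs,
d_cc), with rest lengths l_cs = l_cc = 0.005.  Bonds are stateless: they
are rebuilt from positions every step, so "breaking" is simply leaving the
range.  Substrate bonds are mutual-nearest-neighbor exclusive (a substrate
node links only its closest cell node and vice versa); cell-cell bonds
have no exclusivity — the force is a double sum over all qualifying node
pairs of distinct cells.  Pairs closer than l_cc repel with a fixed
strength R_cc, independent of the adhesion strength, so arbitrarily small
cell-cell adhesions can be probed without cells interpenetrating.

**Gravity.**  Nodes of cells without a contact path to the substrate
(through any bond chain) receive a small constant downward force C_G;
grounded cells are exempt, as appropriate at low Reynolds number.

**Active spreading.**  Once at least 10% of a cell's nodes hold substrate
bonds, the node immediately flanking the outermost substrate connection on
each side receives a constant force C_s directed 45 degrees outward and
below horizontal — a minimal lamellipodium.  Spreading is contact
inhibited per side: a side whose cell has an attractive cell-cell bond to
a neighbor on that side (partner centroid at lower/higher x) is switched
off independently of the other side.

**Adhesion crosstalk feedback.**  A cell holding at least one attractive
cell-cell bond gets gamma_cc -> gamma_cc (1 + 0.03 N_sub) where N_sub is
its substrate-bond count, gamma_cs -> 1.5 gamma_cs, and d_cc -> 1.2 d_cc,
modeling contact-induced cortical remodeling and the increased range over
which touching cells capture neighbors.

**Cortical remodeling.**  Each step, edges longer than twice the cell's
reference node spacing are bisected and edges shorter than half of it lose
the endpoint closest to its other neighbor (never dropping below 8 nodes).
The reference spacing is frozen at construction; using the instantaneous
mean would let the target discretization drift as cells stretch.

**Division.**  Over the final hour of its cycle a proliferative cell ramps
its preferred area linearly from A0 to 2 A0 and sets its own gamma_cc to 0
(adhesion cessation; the R_cc repulsion stays on, since repulsion is
adhesion-independent).  At cycle end the polygon is split along the chord
from its topmost to its bottommost node — a planar, apical-basal division —
and each daughter keeps its arc plus the chord endpoints, then remeshes
until the cytokinetic plane is populated at the reference spacing.
Daughters restart at age 0 with preferred area A0.  Initial cell-cycle
lengths can be drawn uniformly from [0, 4] h; the shipped division
scenario instead seeds a defined central cycle so exactly the central cell
divides, and its daughters are non-proliferative by default.

## Parameters

Non-dimensional defaults (model units: A0 = 1, so 1 length unit = 10 um
for a ~100 um^2 MDCK cross-section; spring strengths scale as 0.1 unit =
20 N/m):

| symbol | meaning | default | dimensional |
|---|---|---|---|
| k_A | area stiffness | 1 | ~2e7 N/m^2 |
| k_L | cortical stiffness | 0.0005 | ~0.1 N/m |
| gamma_cc | cell-cell adhesion | 0.001 | ~0.2 N/m |
| R_cc | cell-cell repulsion | 0.05 | ~10 N/m |
| gamma_cs | cell-substrate adhesion | 0.1 | ~20 N/m |
| d_cc, d_cs | interaction ranges | 0.16, 0.1 | 1.6, 1 um |
| l_cc, l_cs | spring rest lengths | 0.005 | 50 nm |
| C_s | spreading strength | 0.008 | ~16 uN |
| C_G | gravity strength | 0.001 | ~2 uN |
| dt, beta | timestep, drag | 1, 1 | 750 steps = 1 h |

The drag coefficient beta has no independent printed value; it only
rescales time jointly with dt, and the time axis is anchored instead by
the 750-steps-per-hour calibration, so beta = 1 is fixed by convention.
The spreading strength can be held constant, scaled linearly with
gamma_cs / gamma_cs0, or scaled as (gamma_cs / gamma_cs0)^0.2
(nonlinear), with gamma_cs0 = 0.1 the reference adhesion.

## Numerical choices

* Simulation in the non-dimensional parameter column avoids the ~1e7
  stiffness scale of the dimensional units.
* With the default parameters, per-step node displacements stay below 0.05
  length units in all shipped scenarios (monitored by the engine); dt = 1
  is comfortably inside the explicit-Euler stability region of the
  stiffest spring (the boosted substrate adhesion, rate 0.15/step).
* Evaluation order per step: remodel -> division program -> bond matching
  -> feedback -> forces -> Euler move.  Feedback uses the current step's
  contact flags with the previous step's N_sub, and the effective d_cc it
  produces is the matching range of the *next* step; this one-step lag
  makes the feedback well-defined within a step.
* Cell-cell pair forces use strength min(gamma_i_eff, gamma_j_eff).  The
  per-node force law reads each cell's own gamma, which would violate
  Newton's third law whenever effective adhesions differ (feedback boost,
  or a dividing cell with gamma_cc = 0); the minimum keeps pair forces
  equal-and-opposite and makes adhesion cessation binding on both
  partners.  Bond existence uses max(d_cc_i_eff, d_cc_j_eff) so it is
  symmetric too.
* Degenerate geometry (zero-length edges, coincident bonded nodes)
  contributes zero force with a warning rather than NaN; non-finite forces
  abort the run with a diagnostic.
* Ties in mutual-nearest substrate matching break toward the
  first-indexed cell node, making runs bit-reproducible.

## Scenarios and the synthetic study conditions

All inputs are generated in code; there is no external data.  Cells start
as regular 100-gons of unit area dropped one diameter above a substrate
centered on x = 0 and confined only by the substrate's length (no walls —
spreading halts where no bonds can form).  Two placement regimes are used:

* `two_cell` and `three_cell_division` drop cells adjacent (cortices just
  outside d_cc), the "cells landing in proximity" setting.
* `four_cell_confined` — the densification workhorse — plates cells
  sparsely, 2.0 length units (20 um) between centers, clipped to fit short
  substrates.  Sparse plating lets each cell flatten before first touching
  its neighbors; if interior cells instead start within contact range,
  per-side contact inhibition freezes them at the round passive shape and
  the low-density (Immature) regime cannot exist at any substrate length.

Density is controlled solely by substrate length.  The default sweep uses
12 lengths targeting 1.5-9 Arb; density is reported from the realized
occupied span (outermost substrate-bonded nodes), as linear density
converted by Arb = (cells/mm)^2 / 1000, anchored by the correspondence of
~7 Arb with ~7e3 cells/mm^2 MDCK layers.  Sweeps run 24 h-equivalent
(18,000 steps) and summarize the final hour.  The adhesion sweeps
(spreading-scaling modes x gamma_cs values) evaluate the most confined
substrate of the sub-7-Arb grid (~6.5 Arb target), the density regime the
densification analysis is restricted to.

What the generator does *not* emulate: cell heterogeneity (all cells share
one parameter set), stochastic protrusion dynamics (spreading is a
constant force), 3D packing, apical contractility gradients and hence
Mature (flat-apex) architecture, and cell death/extrusion.  Passing tests
therefore show that crowding, adhesion and spreading reproduce the
Immature/Intermediate series in cross-section — not that the model
captures full 3D monolayer mechanics.

## Metrics

* f_cs / f_cc: fraction of a cell's nodes holding >= 1 substrate bond /
  >= 1 attractive cell-cell bond — proxies for basal and lateral interface
  lengths.  With ~100 nodes and d_cc = 0.16, a single real cell-cell
  border (more than one spring between two cells) engages about 10% of a
  cell's nodes, which is the Immature/Intermediate classification
  threshold (boundary value classifies Intermediate).
* Classification averages f_cc over interior cells only; colony-edge cells
  are Immature by construction (one free flank) and enter only the density
  denominator.  The apical:basal summary is also interior-only: edge cells
  bulge over the substrate ends, truncating their basal surface.
* Apical:basal ratio: basal = polyline length over edges between
  substrate-bonded nodes; apical = length over edges whose nodes hold
  neither substrate nor cell-cell bonds (surfaces defined by exclusion
  from cell-cell borders); ratio = apical / basal.
* Shape index S0 = perimeter / sqrt(area) = sqrt(4 pi / circularity).
  The formula is stated here under the square root; the dimensionally
  consistent reading reproduces both reference values (3.81 at the
  vertex-model jamming point, 3.87 at the 0.84 circularity plateau).
* Transition density: first linear-interpolated crossing of the 10%
  threshold along a density-sorted sweep.  Ratio turning density:
  parabolic interpolation through the grid argmax of the apical:basal
  curve (grid endpoint if the maximum sits there).

## Problem sizes

Default runs use 100 nodes/cell (the model is insensitive to node count;
100 keeps "more than one connection" at a few percent of nodes), 4-cell
colonies, 18,000 steps (24 h) per densification run, 12-point density
grids, and 5-6 point adhesion grids.  A full densification sweep takes a
few minutes on one core; the complete acceptance recomputation (23 runs)
about ten.

## Known limitations

* Sweeps at the lowest densities are kinetics-limited: cells are still
  spreading slowly at 24 h, so realized density exceeds the substrate's
  capacity floor; the reported density is the realized one.
* Mature architecture (apical flattening) is out of the model's scope; at
  densities beyond ~9 Arb cells begin to lose substrate contact and the
  monolayer assumption degrades.
* The double-sum cell-cell force makes effective inter-cell adhesion scale
  with the local bond multiplicity (several springs per node within the
  1.6 um range), so gamma_cc is not directly a per-contact stiffness.
* Trajectories store bond tables per frame; metrics recomputed offline
  from a stored trajectory match the online values exactly only because
  bonds are stored, not re-derived (re-deriving would need each frame's
  effective interaction ranges).
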