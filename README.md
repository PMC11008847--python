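# epilayer

A 2D polyline ("deformable polygon") cell-based simulator of epithelial
architecture in the apical-basal plane, for studying how cell crowding,
cell-cell adhesion, cell-substrate adhesion and active spreading shape a
cultured monolayer's cross-section.

Cultured epithelial layers pass through a developmental series of
architectures as they densify: *Immature* (flat, spread cells without
lateral borders), *Intermediate* (taller cells with defined lateral
cell-cell borders), and eventually *Mature* (flattened apices — outside
this model's scope).  `epilayer` asks how much of that series follows from
mechanics alone.  Each cell's cortex in the XZ cross-section is a closed
polyline of ~100 nodes above a rigid, discretized substrate line; nodes
move by overdamped explicit-Euler dynamics (`F = beta v`, `dt = 1`, 750
steps per culture hour) under five forces:

* internal area-perimeter elasticity, `E = 1/2 k_A (A - A0)^2 + 1/2 k_L L^2`
* cell-substrate springs (mutual-nearest pairs within range `d_cs`)
* cell-cell springs (all pairs within `d_cc`; fixed repulsion `R_cc`
  inside the rest length, so adhesion can be made arbitrarily weak)
* an active spreading force `C_s` at 45° outward/down on the nodes
  flanking the outermost substrate contacts, activated once 10% of nodes
  touch the substrate and contact-inhibited per cell side
* a small gravity `C_G` on cells without a contact path to the substrate

plus adhesion crosstalk (cell-cell contact boosts `gamma_cc` with the
substrate-bond count, `gamma_cs` by 1.5x, and the capture range `d_cc` by
1.2x), cortical remodeling that keeps the discretization uniform, and
planar cell division along the top-to-bottom chord with remeshing of the
cytokinetic plane.

Layers are measured by the fraction of each cell's nodes in substrate
(f_cs) and cell-cell (f_cc) adhesion, cell density in arbitrary units
(Arb = (cells/mm)^2 / 1000), and the apical:basal surface-length ratio.
A layer whose interior cells average f_cc >= 10% is classified
Intermediate.  See `docs/methods.md` for the full model description and
the numerical choices.

## Worked example

Confine a four-cell colony to progressively shorter substrates and watch
lateral borders appear (`python examples/03_densification_transition.py`):

```
 substrate_length  density_arb  mean_f_cs  mean_f_cc        label
             10.3     2.317792   0.391526   0.015694     Immature
              7.3     3.008807   0.385416   0.068002     Immature
              5.4     5.465426   0.347259   0.394613 Intermediate

Interpolated Immature->Intermediate crossing at 3.25 Arb (~3.2e3 cells/mm^2 equivalent).
```

At ~2.3 Arb the interior cells keep 39% of their nodes on the substrate
and under 2% on neighbors — flat, substrate-dominated Immature cells.
Shortening the substrate to 5.4 length units (54 um for four cells) drives
the realized density to ~5.5 Arb and pushes 39% of interior nodes into
lateral adhesion: the layer has crossed the 10% threshold and classifies
as Intermediate purely through crowding.  Weakening cell-cell adhesion by
two orders of magnitude moves the crossing to higher density without
abolishing it.

Other examples: single-cell spreading versus passive rounding
(`01_single_cell_spreading.py`), the two-cell plating configuration
(`02_two_cell_plating.py`), division pressure creating lateral borders at
a colony's center (`04_division_pressure.py`), and the shape index
`S0 = sqrt(4 pi / circularity)` linking the circularity plateau to the
vertex-model jamming point (`05_shape_index.py`).

A thin CLI wraps the same API:

```
epilayer run four_cell_confined --steps 18000 --substrate-length 6.0 --out run/
epilayer metrics run/trajectory.npz --out metrics.csv
epilayer render run/trajectory.npz --out frames/
epilayer sweep --gamma-cc 0.00001,0.001,0.1 --out sweep.csv
```

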