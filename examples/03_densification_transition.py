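"""Densification drives the Immature -> Intermediate transition.

A four-cell colony is confined to progressively shorter substrates; when
the mean cell-cell connection fraction of interior cells reaches 10%, the
layer is classified Intermediate.  (Three short runs here; the full
12-point, 24 h sweep lives in the acceptance script.)
"""

from epilayer import ModelParams
from epilayer.sweep import densification_sweep, sweep_transition_density

params = ModelParams()
df = densification_sweep(params, substrate_lengths=[10.3, 7.3, 5.4],
                         hours=12.0, seed=0)
print(df[["substrate_length", "density_arb", "mean_f_cs", "mean_f_cc",
          "label"]].to_string(index=False))

crossing = sweep_transition_density(df)
if crossing is not None:
    print(f"\nInterpolated Immature->Intermediate crossing at "
          f"{crossing:.2f} Arb (~{crossing:.1f}e3 cells/mm^2 equivalent).")
else:
    print("\nNo crossing of the 10% cell-cell connection threshold in "
          "this short sweep.")
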