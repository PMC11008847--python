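"""A single cell dropped onto a substrate, with and without active spreading.

Substrate adhesion alone leaves a cell rounded; the active lamellipodial
force flattens it into the fried-egg shape of isolated cultured cells.
"""

from epilayer import ScenarioConfig, run_scenario

for scenario in ("single_cell_no_spreading", "single_cell_spreading"):
    config = ScenarioConfig(scenario=scenario, substrate_length=10.0,
                            total_steps=9000, record_stride=1500,
                            store_frames=False)
    result = run_scenario(config)
    cell = result.final_state.cells[0]
    print(f"{scenario}: after {config.total_steps / 750:.0f} h-equivalent, "
          f"aspect ratio (width/height) = {cell.aspect_ratio():.2f}")

print("\nAn aspect ratio near 1 means the cell stayed rounded; above 2 it "
      "has flattened and spread along the substrate.")
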