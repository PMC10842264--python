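"""Simulate a density map from a synthetic model and estimate resolution.

Builds a 3-helix bundle, renders it at 6 Å on a 2.612 Å/voxel grid, makes a
noisy low-passed copy, and reads the FSC=0.143 resolution off the curve.
"""

from voxmatch import (
    SimulationParams,
    add_noise,
    fsc,
    lowpass_filter,
    make_helix_bundle,
    resolution_at,
    simulate_map,
)

bundle = make_helix_bundle(3, 30, spacing=10.0, seed=7)
print(f"model: {bundle.model_id}, {bundle.n_atoms} C-alpha atoms")

grid = simulate_map(bundle, SimulationParams(resolution=6.0,
                                             voxel_size=2.612))
print(f"simulated map: dims {grid.dims}, voxel {grid.voxel_size} Å; "
      f"integral {grid.values.sum() * grid.voxel_size**3:.2f} "
      f"(= number of unit-weight atoms)")

# a degraded copy: low-passed to 10 Å plus mild noise
degraded = add_noise(lowpass_filter(grid, 10.0),
                     sigma=0.1 * grid.values.max(), seed=1)
curve = fsc(grid, degraded)
print(f"FSC=0.143 resolution of the degraded copy: "
      f"{resolution_at(curve, 0.143):.2f} Å")
print("(the crossing tracks where the 10 Å filter pushes the per-shell "
      "signal below the noise)")
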