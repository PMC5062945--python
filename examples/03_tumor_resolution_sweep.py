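"""Voxel-size sweep and hypoxic fractions on a tumor-like bed.

Generates a tortuous, branching vessel network in the 990 x 810 x 150 µm³
window-chamber domain, solves the reference oxygen field (takes about a
minute), then sweeps imaging voxel sizes from 50 to 300 µm.  Larger voxels
translate the grid randomly (within half a voxel) and pool the maps.  Also
applies the six-neighbor correction at 50 µm and prints the tumor
hypoxic-fraction regression.
"""

import numpy as np

from oxyfuse import discretize, generate_tumor_like_network, solve_reference_field, tumor_params
from oxyfuse.evaluation import (
    TUMOR_HF_THRESHOLDS,
    hf_correlation,
    linear_regression,
    nearest_neighbor_correction,
)
from oxyfuse.fusion import grid_translation_ensemble, make_voxel_grid, run_fusion

params = tumor_params()
net = generate_tumor_like_network(seed=3)
print(f"network: {len(net.segments)} segments, vascular fraction "
      f"{net.total_vascular_volume() / np.prod(net.domain_box[1] - net.domain_box[0]):.1%}")
lattice, sources = discretize(net)
solution = solve_reference_field(net, lattice, sources, params)
print(f"reference solved in {solution.iterations} iterations; "
      f"tissue pO2 mean {lattice.lpo2.mean():.1f} mmHg "
      f"({(lattice.lpo2 < 5).mean():.0%} of lattice below 5 mmHg)")

for L in (50.0, 100.0, 150.0, 200.0, 250.0, 300.0):
    n_off = 5 if L >= 200 else 1
    table = grid_translation_ensemble(net, lattice, L, params,
                                      n_offsets=n_off, seed=3)
    sub = table[table["valid"]]
    reg = linear_regression(sub)
    print(f"L={L:3.0f} µm ({n_off} grid placement(s)): n={reg.n_points:4d}  "
          f"slope={reg.slope:5.2f}  r²={reg.r_squared:.2f}")
print("-> accuracy peaks at intermediate voxel sizes and collapses beyond "
      "~200 µm, where one effective vessel can no longer stand in for the bed.")

grid = make_voxel_grid(net.domain_box, 50.0)
maps = run_fusion(net, lattice, grid, params)
corrected, _ = nearest_neighbor_correction(maps.mpo2, maps.valid)
before = linear_regression(maps.gpo2[maps.valid], maps.mpo2[maps.valid])
after = linear_regression(maps.gpo2[maps.valid], corrected[maps.valid])
print(f"six-neighbor correction at 50 µm: r² {before.r_squared:.2f} -> "
      f"{after.r_squared:.2f} (neighboring vessels feed oxygen across voxel faces)")

table150 = grid_translation_ensemble(net, lattice, 150.0, params, seed=3)
sub = table150[table150["valid"]]
hf = hf_correlation(sub["mpo2"].to_numpy(), sub["gpo2"].to_numpy(),
                    TUMOR_HF_THRESHOLDS)
print(f"hypoxic-fraction ladder (2.5-15 mmHg) at 150 µm: "
      f"slope={hf.slope:.2f}, r²={hf.r_squared:.2f}")
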