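"""Fusion fidelity at imaging resolution on a parallel vessel array.

A 5x5 array of straight vessels (125 µm spacing, smoothly varying inlet
saturations) stands in for a regular microvascular bed.  Each imaging voxel
is reduced to effective inputs (fvv, r_c, F, SaO2) and run through the
voxel model; the scatter of MPO2 against the reference GPO2 shows how well
a single effective vessel represents the local vasculature.
"""

from oxyfuse import discretize, generate_parallel_array, solve_reference_field, tumor_params
from oxyfuse.evaluation import linear_regression
from oxyfuse.fusion import make_voxel_grid, run_fusion

params = tumor_params()
net = generate_parallel_array(25, spacing=125.0, jitter=10.0, length=100.0,
                              inlet_sao2_range=(0.75, 0.95), seed=11)
lattice, sources = discretize(net)
solution = solve_reference_field(net, lattice, sources, params)
print(f"solved {len(sources)} subsegments; conservation error "
      f"{solution.conservation_error:.2%}")

for L in (50.0, 100.0):
    grid = make_voxel_grid(net.domain_box, L)
    maps = run_fusion(net, lattice, grid, params)
    reg = linear_regression(maps.scatter_table().query("valid"))
    print(f"voxel edge {L:g} µm: n={reg.n_points}, slope={reg.slope:.2f}, "
          f"intercept={reg.intercept:.1f} mmHg, r²={reg.r_squared:.2f}")
print("-> slope near 1 with high r² means the fused voxel estimate tracks the "
      "detailed microvascular reference at these resolutions.")
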