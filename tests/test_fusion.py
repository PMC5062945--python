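"""Fusion pipeline: voxel grids, effective imaging inputs, map generation."""

import numpy as np
import pytest

from oxyfuse.fusion import (
    VoxelInputs,
    effective_voxel_inputs,
    grid_translation_ensemble,
    make_voxel_grid,
    run_fusion,
)
from oxyfuse.physiology import hill_inverse, hill_saturation
from oxyfuse.vasculature import Node, Segment, VesselNetwork


def test_grid_covers_paper_domain():
    grid = make_voxel_grid([[0, 0, 0], [990.0, 810.0, 150.0]], 200.0)
    assert grid.dims[0] == 5  # 990 µm axis: 4 full voxels + a partial fifth
    assert grid.dims == (5, 5, 1)


def test_grid_offset_bounds():
    box = [[0, 0, 0], [300.0, 300.0, 150.0]]
    grid = make_voxel_grid(box, 150.0, offset=(70.0, 0.0, 0.0))
    assert np.all(grid.origin <= 0.0)
    with pytest.raises(ValueError, match="offset"):
        make_voxel_grid(box, 150.0, offset=(75.0, 0.0, 0.0))


def test_half_open_voxel_indexing():
    grid = make_voxel_grid([[0, 0, 0], [100.0, 100.0, 100.0]], 50.0)
    idx = grid.voxel_index(np.array([[50.0, 0.0, 0.0]]))  # boundary -> upper voxel
    assert tuple(idx[0]) == (1, 0, 0)


def two_segment_voxel_network(params):
    """Two axial vessels in one 100 µm voxel with volume ratio 2:3."""
    r1 = 4.0
    r2 = r1 * np.sqrt(1.5)  # volumes 2:3 at equal length
    nodes = [
        Node(0, [0, 30, 50], "inlet", boundary_pressure=20.0, inlet_sao2=0.9),
        Node(1, [100, 30, 50], "outlet", boundary_pressure=5.0),
        Node(2, [0, 70, 50], "inlet", boundary_pressure=20.0, inlet_sao2=0.9),
        Node(3, [100, 70, 50], "outlet", boundary_pressure=5.0),
    ]
    segs = [Segment(0, 0, 1, radius=r1, flow=1e4), Segment(1, 2, 3, radius=r2, flow=2e4)]
    net = VesselNetwork(nodes, segs, [[0, 0, 0], [100.0, 100.0, 100.0]])
    # lumen profiles as the reference solver would leave them
    net.subsegment_po2 = {
        0: [(np.array([50.0, 30, 50]), 100.0, hill_inverse(0.8, params))],
        1: [(np.array([50.0, 70, 50]), 100.0, hill_inverse(0.6, params))],
    }
    return net


def test_volume_weighted_voxel_saturation(params):
    net = two_segment_voxel_network(params)
    vi = effective_voxel_inputs(net, net.domain_box, 100.0, params)
    # SaO2 = (0.8·2 + 0.6·3)/5
    assert vi.sao2_in == pytest.approx(0.68, abs=1e-9)
    assert vi.P_in == pytest.approx(hill_inverse(0.68, params))
    assert min(0.6, 0.8) <= vi.sao2_in <= max(0.6, 0.8)


def test_single_spanning_vessel_is_exact(params):
    nodes = [
        Node(0, [0, 50, 50], "inlet", boundary_pressure=20.0, inlet_sao2=0.85),
        Node(1, [100, 50, 50], "outlet", boundary_pressure=5.0),
    ]
    net = VesselNetwork(nodes, [Segment(0, 0, 1, radius=6.0, flow=5e4)],
                        [[0, 0, 0], [100.0, 100.0, 100.0]])
    net.subsegment_po2 = {0: [(np.array([50.0, 50, 50]), 100.0,
                               hill_inverse(0.85, params))]}
    vi = effective_voxel_inputs(net, net.domain_box, 100.0, params)
    assert vi.rc_eff == pytest.approx(6.0, rel=1e-12)
    assert vi.F_eff == pytest.approx(5e4 / 100.0**3, rel=1e-12)
    assert vi.fvv == pytest.approx(np.pi * 36 * 100 / 100.0**3, rel=1e-12)
    assert vi.sao2_in == pytest.approx(0.85)


def test_empty_voxel_is_invalid(params):
    net = two_segment_voxel_network(params)
    vi = effective_voxel_inputs(net, [[0, 0, 200], [100, 100, 300]], 100.0, params)
    assert not vi.valid
    assert VoxelInputs.invalid().fvv == 0.0


def test_fvv_accounts_for_total_vascular_volume(parallel_solved, params):
    """Σ fvv·V_tissue over any translated grid equals the vascular volume."""
    net, _lat, _src, _sol = parallel_solved
    rng = np.random.default_rng(4)
    for offset in (np.zeros(3), rng.uniform(-40, 40, 3)):
        grid = make_voxel_grid(net.domain_box, 100.0, offset)
        total = 0.0
        for i in range(grid.dims[0]):
            for j in range(grid.dims[1]):
                for k in range(grid.dims[2]):
                    box = grid.voxel_box((i, j, k))
                    vi = effective_voxel_inputs(net, box, 100.0, params,
                                                domain_box=net.domain_box)
                    if vi.valid:
                        lo = np.maximum(box[0], net.domain_box[0])
                        hi = np.minimum(box[1], net.domain_box[1])
                        total += vi.fvv * np.prod(hi - lo)
        assert total == pytest.approx(net.total_vascular_volume(), rel=1e-6)


def test_run_fusion_krogh_one_voxel(krogh_solved, params):
    net, lattice, _src, _sol = krogh_solved
    grid = make_voxel_grid(net.domain_box, 120.0)
    maps = run_fusion(net, lattice, grid, params)
    assert maps.valid.sum() == 1
    mpo2, gpo2 = maps.mpo2[0, 0, 0], maps.gpo2[0, 0, 0]
    assert mpo2 == pytest.approx(gpo2, rel=0.08)
    table = maps.scatter_table()
    assert len(table) == 1 and bool(table["valid"].iloc[0])


def test_ensemble_reproducible_and_pooled(parallel_solved, params):
    net, lattice, _src, _sol = parallel_solved
    t1 = grid_translation_ensemble(net, lattice, 125.0, params, n_offsets=3, seed=9)
    t2 = grid_translation_ensemble(net, lattice, 125.0, params, n_offsets=3, seed=9)
    assert t1.equals(t2)
    assert sorted(t1["offset_id"].unique()) == [0, 1, 2]
    # first member is the untranslated grid
    single = grid_translation_ensemble(net, lattice, 125.0, params, n_offsets=1, seed=1)
    base = t1[t1["offset_id"] == 0].reset_index(drop=True)
    assert np.allclose(base["mpo2"].fillna(-1), single["mpo2"].fillna(-1))
    # pooled row count is the sum of the per-offset counts
    assert len(t1) == sum((t1["offset_id"] == k).sum() for k in range(3))


def test_all_invalid_grid_warns(params):
    nodes = [
        Node(0, [0, 50, 50], "inlet", boundary_pressure=20.0, inlet_sao2=0.85),
        Node(1, [100, 50, 50], "outlet", boundary_pressure=5.0),
    ]
    net = VesselNetwork(nodes, [Segment(0, 0, 1, radius=6.0, flow=5e4)],
                        [[0, 0, 0], [100.0, 100.0, 100.0]])
    net.subsegment_po2 = {}
    from oxyfuse.reference_solver import TissueLattice

    lattice = TissueLattice.for_domain(net.domain_box, h=50.0)
    lattice.lpo2 = np.full(lattice.dims, 20.0)
    grid = make_voxel_grid(net.domain_box, 100.0)
    with pytest.warns(UserWarning, match="no valid voxels"):
        maps = run_fusion(net, lattice, grid, params)
    assert not maps.valid.any()
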