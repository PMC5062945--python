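"""Vessel networks: I/O round trips, generators, hemodynamics, clipping."""

import numpy as np
import pytest

from oxyfuse.vasculature import (
    Node,
    Segment,
    VesselNetwork,
    brain_network_preset,
    clip_segment_to_box,
    generate_parallel_array,
    generate_single_vessel,
    generate_tumor_like_network,
    read_network,
    solve_hemodynamics,
    write_network,
)

MMHG_TO_MPA = 133322.0


def minimal_network():
    nodes = [
        Node(0, [0.0, 50.0, 50.0], "inlet", boundary_pressure=25.0, inlet_sao2=0.9),
        Node(1, [100.0, 50.0, 50.0], "outlet", boundary_pressure=10.0),
    ]
    return VesselNetwork(nodes, [Segment(0, 0, 1, radius=5.0, flow=1e4)],
                         [[0.0, 0.0, 0.0], [100.0, 100.0, 100.0]])


def assert_networks_equal(a: VesselNetwork, b: VesselNetwork):
    assert len(a.nodes) == len(b.nodes) and len(a.segments) == len(b.segments)
    for na, nb in zip(a.nodes, b.nodes):
        assert na.id == nb.id and na.boundary_role == nb.boundary_role
        np.testing.assert_allclose(na.position, nb.position)
        assert (na.inlet_sao2 is None) == (nb.inlet_sao2 is None)
    for sa, sb in zip(a.segments, b.segments):
        assert (sa.node_from, sa.node_to) == (sb.node_from, sb.node_to)
        assert sa.radius == pytest.approx(sb.radius)
        assert sa.flow == pytest.approx(sb.flow)
    np.testing.assert_allclose(a.domain_box, b.domain_box)


@pytest.mark.parametrize("fmt, path_name", [("csv-pair", "netdir"), ("json", "net.json")])
def test_io_round_trip(tmp_path, fmt, path_name):
    net = minimal_network()
    target = tmp_path / path_name
    write_network(net, target, format=fmt)
    assert_networks_equal(read_network(target, format=fmt), net)


def test_validation_errors():
    with pytest.raises(ValueError, match="missing node"):
        VesselNetwork([Node(0, [0, 0, 0])], [Segment(0, 0, 1, radius=5.0)],
                      [[0, 0, 0], [1, 1, 1]])
    with pytest.raises(ValueError, match="radius"):
        Segment(0, 0, 1, radius=-2.0)
    with pytest.raises(ValueError, match="SaO2"):
        Node(0, [0, 0, 0], "inlet", inlet_sao2=1.5)


def test_single_vessel_geometry():
    net = generate_single_vessel(length=150.0, radius=5.0, flow=1e5)
    seg = net.segments[0]
    assert net.segment_volume(seg) == pytest.approx(np.pi * 25 * 150)
    fvv = net.segment_volume(seg) / 150.0**3
    assert fvv == pytest.approx(np.pi * 25 / 150**2)
    inlet, outlet = net.node_by_id(0), net.node_by_id(1)
    assert inlet.position[0] == 0.0 and outlet.position[0] == 150.0
    assert inlet.boundary_role == "inlet" and outlet.boundary_role == "outlet"


def test_parallel_array_layout_and_determinism():
    net = generate_parallel_array(4, spacing=75.0, jitter=0.0, seed=0)
    xy = np.array([n.position[:2] for n in net.inlets()])
    d = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
    assert d[d > 0].min() == pytest.approx(75.0)

    a = generate_parallel_array(9, spacing=100.0, jitter=10.0, seed=5)
    b = generate_parallel_array(9, spacing=100.0, jitter=10.0, seed=5)
    assert_networks_equal(a, b)

    with pytest.raises(ValueError, match="spacing"):
        generate_parallel_array(4, spacing=10.0, radius_range=(4.0, 8.0))


def test_tumor_network_properties():
    net = generate_tumor_like_network(seed=0)
    np.testing.assert_allclose(net.domain_box, [[0, 0, 0], [990.0, 810.0, 150.0]])
    frac = net.total_vascular_volume() / np.prod(net.domain_box[1] - net.domain_box[0])
    assert 0.8 * 0.02 <= frac <= 1.2 * 0.02
    assert_networks_equal(net, generate_tumor_like_network(seed=0))
    # every segment carries flow (leaf tips drain out of the observed slab)
    assert all(abs(s.flow) > 0 for s in net.segments)
    net.check_flow_conservation(rtol=1e-6)


def test_tumor_network_minimum_separation():
    """Non-adjacent vessels keep a wall-to-wall gap near the 12 µm floor."""
    import networkx as nx

    net = generate_tumor_like_network(seed=1)
    g = nx.Graph()
    for s in net.segments:
        g.add_edge(s.node_from, s.node_to)
    pts, rads, ends = [], [], []
    for s in net.segments:
        a, b = net.segment_endpoints(s)
        for t in np.linspace(0, 1, 5):
            pts.append(a + t * (b - a))
            rads.append(s.radius)
            ends.append((s.node_from, s.node_to))
    pts = np.asarray(pts)
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    worst = np.inf
    for i, j in tree.query_pairs(40.0):
        try:
            dg = min(nx.shortest_path_length(g, a, b) for a in ends[i] for b in ends[j])
        except nx.NetworkXNoPath:
            dg = 99
        if dg <= 3:
            continue
        worst = min(worst, np.linalg.norm(pts[i] - pts[j]) - rads[i] - rads[j])
    assert worst >= 0.8 * 12.0  # mid-step sampling leaves a little slack


def test_brain_preset_domain():
    net = brain_network_preset(seed=0)
    np.testing.assert_allclose(net.domain_box, [[0, 0, 0], [150.0, 160.0, 140.0]])


def test_poiseuille_single_tube():
    net = minimal_network()
    net.segments[0].flow = 0.0
    solve_hemodynamics(net, viscosity=4.0)
    dp = (25.0 - 10.0) * MMHG_TO_MPA
    expected = np.pi * 5.0**4 / (8 * 4.0 * 100.0) * dp
    assert net.segments[0].flow == pytest.approx(expected, rel=1e-9)


def test_symmetric_bifurcation_splits_equally():
    nodes = [
        Node(0, [0, 0, 0], "inlet", boundary_pressure=20.0, inlet_sao2=0.9),
        Node(1, [100, 0, 0], "interior"),
        Node(2, [200, 50, 0], "outlet", boundary_pressure=5.0),
        Node(3, [200, -50, 0], "outlet", boundary_pressure=5.0),
    ]
    segs = [Segment(0, 0, 1, radius=6.0), Segment(1, 1, 2, radius=4.0),
            Segment(2, 1, 3, radius=4.0)]
    net = VesselNetwork(nodes, segs, [[-1, -60, -60], [201, 60, 60]])
    solve_hemodynamics(net)
    assert net.segments[1].flow == pytest.approx(net.segments[2].flow, rel=1e-9)
    assert net.segments[0].flow == pytest.approx(
        net.segments[1].flow + net.segments[2].flow, rel=1e-9)


def test_disconnected_graph_reported():
    nodes = [
        Node(0, [0, 0, 0], "inlet", boundary_pressure=20.0),
        Node(1, [50, 0, 0], "outlet", boundary_pressure=5.0),
        Node(2, [0, 50, 0], "interior"),
        Node(3, [50, 50, 0], "interior"),
    ]
    segs = [Segment(0, 0, 1, radius=5.0), Segment(1, 2, 3, radius=5.0)]
    net = VesselNetwork(nodes, segs, [[-1, -1, -1], [60, 60, 60]])
    with pytest.raises(ValueError, match="disconnected"):
        solve_hemodynamics(net)


def test_clip_trivial_cases():
    box = [[0, 0, 0], [100, 100, 100]]
    assert clip_segment_to_box([10, 50, 50], [90, 50, 50], box) == pytest.approx(80.0)
    assert clip_segment_to_box([-50, 50, 50], [50, 50, 50], box) == pytest.approx(50.0)
    assert clip_segment_to_box([150, 150, 150], [200, 150, 150], box) == 0.0


def test_clip_partition_over_voxel_grid():
    """Clipped lengths over a complete partition sum to the full length."""
    rng = np.random.default_rng(12)
    for _ in range(20):
        p0 = rng.uniform(0, 300, 3)
        p1 = rng.uniform(0, 300, 3)
        total = 0.0
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    lo = np.array([i, j, k]) * 100.0
                    total += clip_segment_to_box(p0, p1, [lo, lo + 100.0])
        assert total == pytest.approx(np.linalg.norm(p1 - p0), rel=1e-9)
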