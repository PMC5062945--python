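"""Vessel-network data model, I/O, synthetic generators and hemodynamics.

Networks are node/segment graphs in µm coordinates.  The synthetic
generators stand in for intravital-microscopy reconstructions of
window-chamber microvasculature: a single Krogh-style capillary, regular
parallel arrays, and a stochastic tortuous tumor-like bed whose
inter-vessel spacing spans roughly 12-125 µm under the defaults.

Conventions: 0-based indices, axis-aligned half-open boxes [lo, hi),
segment flow is signed from ``node_from`` to ``node_to`` in µm³/s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Node",
    "Segment",
    "VesselNetwork",
    "read_network",
    "write_network",
    "generate_single_vessel",
    "generate_parallel_array",
    "generate_tumor_like_network",
    "solve_hemodynamics",
    "clip_segment_to_box",
    "tumor_network_preset",
    "brain_network_preset",
]


@dataclass
class Node:
    id: int
    position: np.ndarray  # (3,) µm
    boundary_role: str = "interior"  # interior | inlet | outlet
    boundary_pressure: float | None = None  # mmHg
    inlet_sao2: float | None = None  # fraction, inlets only

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"node {self.id}: position must be a finite 3-vector")
        if self.boundary_role not in ("interior", "inlet", "outlet"):
            raise ValueError(f"node {self.id}: bad role {self.boundary_role!r}")
        if self.boundary_role == "inlet" and self.inlet_sao2 is not None:
            if not (0.0 < self.inlet_sao2 <= 1.0):
                raise ValueError(f"node {self.id}: inlet SaO2 must be in (0, 1]")


@dataclass
class Segment:
    id: int
    node_from: int
    node_to: int
    radius: float  # µm
    flow: float = 0.0  # µm³/s, signed from->to
    hematocrit: float = 0.45
    blood_po2_in: float | None = None  # mmHg, filled by the reference solver
    blood_po2_out: float | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0 or not np.isfinite(self.radius):
            raise ValueError(f"segment {self.id}: radius must be > 0")
        if not np.isfinite(self.flow):
            raise ValueError(f"segment {self.id}: flow must be finite")


@dataclass
class VesselNetwork:
    nodes: list[Node]
    segments: list[Segment]
    domain_box: np.ndarray  # (2, 3) [[lo], [hi]] µm
    # per-segment list of (midpoint xyz, length, blood pO2); filled by the
    # reference solver and consumed by the fusion stage
    subsegment_po2: dict[int, list[tuple[np.ndarray, float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.domain_box = np.asarray(self.domain_box, dtype=float).reshape(2, 3)
        ids = {n.id for n in self.nodes}
        if len(ids) != len(self.nodes):
            raise ValueError("duplicate node ids")
        for s in self.segments:
            if s.node_from not in ids or s.node_to not in ids:
                raise ValueError(f"segment {s.id} references missing node")
            if s.node_from == s.node_to:
                raise ValueError(f"segment {s.id} is a self-loop")

    # -- convenience accessors ------------------------------------------------
    def node_by_id(self, nid: int) -> Node:
        return self._node_index()[nid]

    def _node_index(self) -> dict[int, Node]:
        if not hasattr(self, "_nidx") or len(self._nidx) != len(self.nodes):
            self._nidx = {n.id: n for n in self.nodes}
        return self._nidx

    def segment_endpoints(self, seg: Segment) -> tuple[np.ndarray, np.ndarray]:
        idx = self._node_index()
        return idx[seg.node_from].position, idx[seg.node_to].position

    def segment_length(self, seg: Segment) -> float:
        a, b = self.segment_endpoints(seg)
        length = float(np.linalg.norm(b - a))
        if length <= 0:
            raise ValueError(f"segment {seg.id} has zero length")
        return length

    def segment_volume(self, seg: Segment) -> float:
        return np.pi * seg.radius**2 * self.segment_length(seg)

    def total_vascular_volume(self) -> float:
        return float(sum(self.segment_volume(s) for s in self.segments))

    def inlets(self) -> list[Node]:
        return [n for n in self.nodes if n.boundary_role == "inlet"]

    def outlets(self) -> list[Node]:
        return [n for n in self.nodes if n.boundary_role == "outlet"]

    def check_flow_conservation(self, rtol: float = 1e-6) -> float:
        """Max relative flow imbalance over interior nodes; raises if > rtol."""
        net_flow: dict[int, float] = {n.id: 0.0 for n in self.nodes}
        scale = max((abs(s.flow) for s in self.segments), default=0.0)
        for s in self.segments:
            net_flow[s.node_from] -= s.flow
            net_flow[s.node_to] += s.flow
        worst = 0.0
        for n in self.nodes:
            if n.boundary_role == "interior":
                worst = max(worst, abs(net_flow[n.id]))
        rel = worst / scale if scale > 0 else 0.0
        if rel > rtol:
            raise ValueError(f"flow imbalance {rel:.2e} exceeds {rtol:.1e}")
        return rel


# ---------------------------------------------------------------------------
# I/O: CSV pair (nodes.csv + segments.csv) or a single JSON document
# ---------------------------------------------------------------------------

_NODE_COLS = ["id", "x", "y", "z", "role", "pressure", "inlet_sao2"]
_SEG_COLS = ["id", "from", "to", "radius_um", "flow_um3_s", "hematocrit"]


def _nodes_frame(net: VesselNetwork) -> pd.DataFrame:
    rows = [
        dict(
            id=n.id, x=n.position[0], y=n.position[1], z=n.position[2],
            role=n.boundary_role,
            pressure=np.nan if n.boundary_pressure is None else n.boundary_pressure,
            inlet_sao2=np.nan if n.inlet_sao2 is None else n.inlet_sao2,
        )
        for n in net.nodes
    ]
    return pd.DataFrame(rows, columns=_NODE_COLS)


def _segments_frame(net: VesselNetwork) -> pd.DataFrame:
    rows = [
        {"id": s.id, "from": s.node_from, "to": s.node_to, "radius_um": s.radius,
         "flow_um3_s": s.flow, "hematocrit": s.hematocrit}
        for s in net.segments
    ]
    return pd.DataFrame(rows, columns=_SEG_COLS)


def _network_from_frames(nodes_df: pd.DataFrame, segs_df: pd.DataFrame,
                         domain: np.ndarray) -> VesselNetwork:
    for col in _NODE_COLS[:5]:
        if col not in nodes_df.columns:
            raise ValueError(f"nodes table missing column {col!r}")
    for col in _SEG_COLS[:4]:
        if col not in segs_df.columns:
            raise ValueError(f"segments table missing column {col!r}")
    nodes = []
    for i, row in nodes_df.iterrows():
        pressure = row.get("pressure", np.nan)
        sao2 = row.get("inlet_sao2", np.nan)
        try:
            nodes.append(Node(
                id=int(row["id"]),
                position=np.array([row["x"], row["y"], row["z"]], dtype=float),
                boundary_role=str(row["role"]),
                boundary_pressure=None if pd.isna(pressure) else float(pressure),
                inlet_sao2=None if pd.isna(sao2) else float(sao2),
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"nodes table row {i}: {exc}") from exc
    segments = []
    for i, row in segs_df.iterrows():
        try:
            segments.append(Segment(
                id=int(row["id"]), node_from=int(row["from"]), node_to=int(row["to"]),
                radius=float(row["radius_um"]),
                flow=float(row.get("flow_um3_s", 0.0) if not pd.isna(row.get("flow_um3_s", 0.0)) else 0.0),
                hematocrit=float(row.get("hematocrit", 0.45)),
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"segments table row {i}: {exc}") from exc
    return VesselNetwork(nodes=nodes, segments=segments, domain_box=domain)


def write_network(net: VesselNetwork, path: str | Path, format: str = "csv-pair") -> None:
    """Write a network as a CSV pair inside directory ``path`` or a JSON file."""
    path = Path(path)
    if format == "csv-pair":
        path.mkdir(parents=True, exist_ok=True)
        _nodes_frame(net).to_csv(path / "nodes.csv", index=False)
        _segments_frame(net).to_csv(path / "segments.csv", index=False)
        (path / "domain.json").write_text(json.dumps({"domain": net.domain_box.tolist()}))
    elif format == "json":
        doc = {
            "domain": net.domain_box.tolist(),
            "nodes": _nodes_frame(net).to_dict(orient="records"),
            "segments": _segments_frame(net).to_dict(orient="records"),
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(doc, indent=1, default=float))
    else:
        raise ValueError(f"unknown format {format!r} (csv-pair or json)")


def read_network(path: str | Path, format: str = "csv-pair") -> VesselNetwork:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    if format == "csv-pair":
        nodes_df = pd.read_csv(path / "nodes.csv")
        segs_df = pd.read_csv(path / "segments.csv")
        domain = np.asarray(json.loads((path / "domain.json").read_text())["domain"])
    elif format == "json":
        doc = json.loads(path.read_text())
        nodes_df = pd.DataFrame(doc["nodes"])
        segs_df = pd.DataFrame(doc["segments"])
        domain = np.asarray(doc["domain"])
    else:
        raise ValueError(f"unknown format {format!r} (csv-pair or json)")
    # tolerate NaN-free JSON round trips where optional columns carry None
    for col in ("pressure", "inlet_sao2"):
        if col in nodes_df.columns:
            nodes_df[col] = pd.to_numeric(nodes_df[col], errors="coerce")
    return _network_from_frames(nodes_df, segs_df, domain)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_single_vessel(length: float, radius: float, flow: float,
                           inlet_sao2: float = 0.95,
                           domain_box=None) -> VesselNetwork:
    """One straight vessel along x, centered in ``domain_box``.

    The Krogh fixture: inlet on the low-x face, outlet on the high-x face.
    ``domain_box`` defaults to a cube of edge ``length``.
    """
    if domain_box is None:
        domain_box = np.array([[0.0, 0.0, 0.0], [length, length, length]])
    domain_box = np.asarray(domain_box, dtype=float).reshape(2, 3)
    extent = domain_box[1] - domain_box[0]
    if length > extent[0] + 1e-9:
        raise ValueError("vessel longer than the domain along x")
    cy, cz = domain_box[0][1] + extent[1] / 2, domain_box[0][2] + extent[2] / 2
    x0 = domain_box[0][0] + (extent[0] - length) / 2
    nodes = [
        Node(0, np.array([x0, cy, cz]), "inlet", boundary_pressure=25.0, inlet_sao2=inlet_sao2),
        Node(1, np.array([x0 + length, cy, cz]), "outlet", boundary_pressure=10.0),
    ]
    segments = [Segment(0, 0, 1, radius=radius, flow=flow)]
    return VesselNetwork(nodes, segments, domain_box)


def generate_parallel_array(n_vessels: int, spacing: float, jitter: float = 0.0,
                            radius_range=(4.0, 8.0), inlet_sao2_range=(0.6, 0.95),
                            mean_velocity: float = 1500.0, seed: int = 0,
                            length: float | None = None,
                            margin: float | None = None) -> VesselNetwork:
    """Axis-aligned array of straight vessels on a jittered square grid.

    Vessels run along z through the whole domain; the xy grid has
    ``ceil(sqrt(n))`` columns at ``spacing`` µm.  Radii and (via Poiseuille
    velocity) flows are sampled per vessel with a seeded RNG.  Inlet
    saturations vary smoothly across the array (a diagonal ramp over
    ``inlet_sao2_range`` plus small per-vessel noise): microvessels in a
    real bed branch from common feeding arterioles, so neighbouring
    capillaries carry similar saturations rather than independent ones.
    Reproducible bit-for-bit for a fixed seed.
    """
    if n_vessels < 1:
        raise ValueError("need at least one vessel")
    if spacing <= 2 * max(radius_range):
        raise ValueError("spacing must exceed the vessel diameter")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_vessels)))
    length = 150.0 if length is None else float(length)
    margin = spacing / 2 if margin is None else float(margin)
    lo = np.array([0.0, 0.0, 0.0])
    hi = np.array([2 * margin + (side - 1) * spacing,
                   2 * margin + (side - 1) * spacing, length])
    nodes: list[Node] = []
    segments: list[Segment] = []
    nid = 0
    placed = 0
    for iy in range(side):
        for ix in range(side):
            if placed >= n_vessels:
                break
            x = margin + ix * spacing
            y = margin + iy * spacing
            if jitter > 0:
                x += rng.uniform(-jitter, jitter)
                y += rng.uniform(-jitter, jitter)
            radius = rng.uniform(*radius_range) if n_vessels > 1 else float(np.mean(radius_range))
            if n_vessels > 1:
                s_lo, s_hi = inlet_sao2_range
                ramp = (ix + iy) / max(2 * (side - 1), 1)
                sao2 = float(np.clip(s_lo + (s_hi - s_lo) * ramp
                                     + rng.normal(0.0, 0.02), 0.05, 0.999))
            else:
                sao2 = float(np.mean(inlet_sao2_range))
            velocity = mean_velocity * rng.uniform(0.5, 1.5) if n_vessels > 1 else mean_velocity
            flow = velocity * np.pi * radius**2
            nodes.append(Node(nid, np.array([x, y, 0.0]), "inlet",
                              boundary_pressure=25.0, inlet_sao2=sao2))
            nodes.append(Node(nid + 1, np.array([x, y, length]), "outlet",
                              boundary_pressure=10.0))
            segments.append(Segment(placed, nid, nid + 1, radius=radius, flow=flow))
            nid += 2
            placed += 1
    return VesselNetwork(nodes, segments, np.array([lo, hi]))


def generate_tumor_like_network(domain_box=None, target_vascular_fraction: float = 0.02,
                                branch_prob: float = 0.12, radius_range=(3.0, 15.0),
                                tortuosity: float = 0.35, step: float = 45.0,
                                inlet_sao2_range=(0.65, 0.95),
                                total_inflow: float | None = 230.37e6 / 60.0,
                                min_separation: float = 12.0,
                                seed: int = 0, max_paths: int = 400) -> VesselNetwork:
    """Stochastic tortuous vessel bed emulating a window-chamber tumor.

    Tortuous paths march across the domain from the low-x face, jittering
    transversely (``tortuosity`` sets the transverse step fraction) and
    branching with probability ``branch_prob`` per step.  Paths avoid one
    another: a step that would bring a vessel within ``min_separation``
    (default 12 µm wall-to-wall, the low end of measured inter-vessel
    spacing) of a previously placed vessel is re-aimed a few times and the
    path is terminated if no clearance is found — vessels never cross.
    Paths are added until the vascular volume reaches
    ``target_vascular_fraction`` of the domain.  Flows come from a
    Poiseuille pressure solve whose boundary pressures are rescaled so
    total inflow matches ``total_inflow`` (default 230.37 nL/min, the
    tumor preset).

    Default domain is 990 x 810 x 150 µm³ (the tumor window-chamber field
    of view).  Raises if the volume target cannot be met in ``max_paths``.
    """
    if domain_box is None:
        domain_box = np.array([[0.0, 0.0, 0.0], [990.0, 810.0, 150.0]])
    domain_box = np.asarray(domain_box, dtype=float).reshape(2, 3)
    lo, hi = domain_box
    extent = hi - lo
    rng = np.random.default_rng(seed)
    target_volume = target_vascular_fraction * float(np.prod(extent))

    nodes: list[Node] = []
    segments: list[Segment] = []
    volume = 0.0
    nid = 0
    sid = 0

    def add_node(pos, role, sao2=None, pressure=None) -> int:
        nonlocal nid
        nodes.append(Node(nid, np.asarray(pos, dtype=float), role,
                          boundary_pressure=pressure, inlet_sao2=sao2))
        nid += 1
        return nid - 1

    # occupied space: sample points along placed segments, for clearance tests
    occupied_pos: list[np.ndarray] = []
    occupied_rad: list[float] = []
    occupied_path: list[int] = []
    occupied_step: list[int] = []

    def record_occupancy(p0: np.ndarray, p1: np.ndarray, radius: float,
                         path_id: int, step_idx: int) -> None:
        n_pts = max(2, int(np.ceil(np.linalg.norm(p1 - p0) / (min_separation / 2))))
        for t in np.linspace(0.0, 1.0, n_pts):
            occupied_pos.append(p0 + t * (p1 - p0))
            occupied_rad.append(radius)
            occupied_path.append(path_id)
            occupied_step.append(step_idx)

    def clearance_ok(tip: np.ndarray, candidate: np.ndarray, radius: float,
                     path_id: int, step_idx: int, origin: np.ndarray) -> bool:
        # exempt: the path's own last three steps (a path may not curl back
        # onto its older trail) and the parent trail near the branch origin;
        # the step is sampled so vessels cannot cross mid-step either
        if not occupied_pos:
            return True
        pos_arr = np.asarray(occupied_pos)
        rad_arr = np.asarray(occupied_rad)
        exempt = ((np.asarray(occupied_path) == path_id)
                  & (np.asarray(occupied_step) >= step_idx - 3))
        exempt |= np.linalg.norm(pos_arr - origin, axis=1) <= step
        check = ~exempt
        if not check.any():
            return True
        limit = rad_arr[check] + radius + min_separation
        for t in (0.34, 0.67, 1.0):
            p = tip + t * (candidate - tip)
            d = np.linalg.norm(pos_arr[check] - p, axis=1)
            if np.any(d < limit):
                return False
        return True

    path_counter = [0]

    def march(start_node: int, start_pos: np.ndarray, radius: float, depth: int) -> None:
        """Grow one tortuous path in +x until it leaves the domain."""
        nonlocal volume, sid
        path_counter[0] += 1
        path_id = path_counter[0]
        origin = start_pos.copy()
        pos = start_pos.copy()
        prev = start_node
        direction = np.array([1.0, 0.0, 0.0])
        for step_idx in range(200):
            new_pos = None
            exited = False
            for _attempt in range(6):
                jitter = rng.normal(0.0, tortuosity, size=3)
                jitter[0] = 0.0
                cand_dir = direction + jitter
                cand_dir[0] = abs(cand_dir[0]) + 0.2  # keep marching downstream
                cand_dir /= np.linalg.norm(cand_dir)
                cand = pos + cand_dir * step
                inside = np.all(cand > lo) and np.all(cand < hi)
                if clearance_ok(pos, cand, radius, path_id, step_idx, origin):
                    direction, new_pos = cand_dir, cand
                    exited = not inside
                    break
            if new_pos is None:
                break  # boxed in: stop this path
            if exited:
                # clip the last step to the domain boundary
                t = np.inf
                for ax in range(3):
                    d = direction[ax] * step
                    if d > 0:
                        t = min(t, (hi[ax] - pos[ax]) / d)
                    elif d < 0:
                        t = min(t, (lo[ax] - pos[ax]) / d)
                t = max(min(t, 1.0), 1e-3)
                new_pos = pos + direction * step * t
            seg_len = float(np.linalg.norm(new_pos - pos))
            if seg_len < 1.0:
                break
            role = "outlet" if exited else "interior"
            nxt = add_node(new_pos, role, pressure=0.0 if exited else None)
            segments.append(Segment(sid, prev, nxt, radius=radius))
            sid += 1
            volume += np.pi * radius**2 * seg_len
            record_occupancy(pos, new_pos, radius, path_id, step_idx)
            if exited:
                return
            # occasional side branch with a thinner child vessel
            if depth < 3 and rng.uniform() < branch_prob:
                child_r = max(radius_range[0], radius * rng.uniform(0.6, 0.85))
                march(nxt, new_pos.copy(), child_r, depth + 1)
            prev, pos = nxt, new_pos

    def start_clear(p: np.ndarray, radius: float) -> bool:
        if not occupied_pos:
            return True
        d = np.linalg.norm(np.asarray(occupied_pos) - p, axis=1)
        return bool(np.all(d >= np.asarray(occupied_rad) + radius + min_separation))

    n_paths = 0
    while volume < target_volume:
        if n_paths >= max_paths:
            raise RuntimeError(
                f"could not reach vascular fraction {target_vascular_fraction} "
                f"within {max_paths} paths (reached {volume / np.prod(extent):.4f})")
        radius = rng.uniform(*radius_range)
        start = None
        for _try in range(50):
            cand = np.array([lo[0],
                             rng.uniform(lo[1] + 20, hi[1] - 20),
                             rng.uniform(lo[2] + 15, hi[2] - 15)])
            if start_clear(cand, radius):
                start = cand
                break
        if start is None:
            raise RuntimeError(
                f"no clear inlet position left for vascular fraction "
                f"{target_vascular_fraction} (reached {volume / np.prod(extent):.4f})")
        root = add_node(start, "inlet", sao2=rng.uniform(*inlet_sao2_range), pressure=1.0)
        march(root, start, radius, depth=0)
        n_paths += 1

    # every leaf tip drains: either it left the domain or it stands for a
    # vessel diving out of the thin observed slab; this keeps all placed
    # segments perfused, so no stagnant dead ends exist
    has_outgoing = {s.node_from for s in segments}
    has_incoming = {s.node_to for s in segments}
    for n in nodes:
        if n.id in has_incoming and n.id not in has_outgoing:
            n.boundary_role = "outlet"
            n.boundary_pressure = 0.0

    net = VesselNetwork(nodes, segments, domain_box)
    net = solve_hemodynamics(net)
    if total_inflow is not None:
        inflow = sum(abs(s.flow) for s in net.segments
                     if net.node_by_id(s.node_from).boundary_role == "inlet"
                     or net.node_by_id(s.node_to).boundary_role == "inlet")
        if inflow > 0:
            scale = total_inflow / inflow
            for s in net.segments:
                s.flow *= scale
    return net


def tumor_network_preset(seed: int = 0, **kwargs) -> VesselNetwork:
    """Tumor-like network in the 990 x 810 x 150 µm³ window-chamber domain."""
    return generate_tumor_like_network(seed=seed, **kwargs)


def brain_network_preset(seed: int = 0, **kwargs) -> VesselNetwork:
    """Denser, more regular bed in the 150 x 160 x 140 µm³ brain domain.

    Normal cortical capillary beds are tighter and less tortuous than tumor
    vasculature; inter-vessel spacing sits near the low end of the tumor
    range and inlet saturations are uniformly high.
    """
    defaults = dict(
        domain_box=np.array([[0.0, 0.0, 0.0], [150.0, 160.0, 140.0]]),
        target_vascular_fraction=0.03,
        branch_prob=0.05,
        radius_range=(2.5, 5.0),
        tortuosity=0.15,
        step=30.0,
        inlet_sao2_range=(0.85, 0.97),
        total_inflow=10.8e6 / 60.0,
    )
    defaults.update(kwargs)
    return generate_tumor_like_network(seed=seed, **defaults)


# ---------------------------------------------------------------------------
# Hemodynamics
# ---------------------------------------------------------------------------

def solve_hemodynamics(net: VesselNetwork, viscosity: float = 4.0,
                       boundary_pressures: dict[int, float] | None = None) -> VesselNetwork:
    """Poiseuille flow solve: conductance g = π r⁴ / (8 µ L) per segment.

    ``viscosity`` is in mPa·s (cP).  Boundary pressures come from node
    ``boundary_pressure`` fields unless overridden; interior nodes satisfy
    Kirchhoff flow balance.  The solve is linear, so pressures may be in
    arbitrary consistent units — flows scale linearly with ΔP and are
    stored signed from->to in µm³/s when pressure is in mmHg
    (1 mmHg = 133.322e-6 mPa·µm⁻²·... handled via a consistent constant).

    Raises on a disconnected graph (naming the components without a
    boundary node) or if fewer than one inlet and one outlet exist.
    """
    import networkx as nx
    from scipy.sparse import coo_matrix
    from scipy.sparse.linalg import spsolve

    pressures = dict(boundary_pressures or {})
    for n in net.nodes:
        if n.boundary_role in ("inlet", "outlet") and n.id not in pressures:
            if n.boundary_pressure is None:
                raise ValueError(f"boundary node {n.id} has no pressure")
            pressures[n.id] = n.boundary_pressure
    if not any(net.node_by_id(i).boundary_role == "inlet" for i in pressures):
        raise ValueError("need at least one inlet with a pressure")
    if not any(net.node_by_id(i).boundary_role == "outlet" for i in pressures):
        raise ValueError("need at least one outlet with a pressure")

    g = nx.Graph()
    g.add_nodes_from(n.id for n in net.nodes)
    g.add_edges_from((s.node_from, s.node_to) for s in net.segments)
    bad = [sorted(c) for c in nx.connected_components(g)
           if not any(nid in pressures for nid in c)]
    if bad:
        raise ValueError(f"disconnected components without boundary pressure: {bad}")

    # mmHg -> Pa: 133.322; µm/mPa·s conversions cancel to give µm³/s directly
    # with g in µm³/(mPa·s) and ΔP in mPa: Q = g·ΔP. 1 mmHg = 133322 mPa? No:
    # 1 mmHg = 133.322 Pa = 133322 mPa. Keep a single constant.
    MMHG_TO_MPA = 133322.0

    idx = {n.id: i for i, n in enumerate(net.nodes)}
    n_nodes = len(net.nodes)
    rows, cols, vals = [], [], []
    rhs = np.zeros(n_nodes)
    conduct = {}
    for s in net.segments:
        L = net.segment_length(s)
        gij = np.pi * s.radius**4 / (8.0 * viscosity * L)  # µm³/(mPa·s)
        conduct[s.id] = gij
        i, j = idx[s.node_from], idx[s.node_to]
        for a, b in ((i, i), (j, j)):
            rows.append(a); cols.append(b); vals.append(gij)
        for a, b in ((i, j), (j, i)):
            rows.append(a); cols.append(b); vals.append(-gij)
    A = coo_matrix((vals, (rows, cols)), shape=(n_nodes, n_nodes)).tocsr().tolil()
    for nid_, p in pressures.items():
        i = idx[nid_]
        A.rows[i] = [i]
        A.data[i] = [1.0]
        rhs[i] = p * MMHG_TO_MPA
    p = spsolve(A.tocsr(), rhs)
    for s in net.segments:
        s.flow = conduct[s.id] * (p[idx[s.node_from]] - p[idx[s.node_to]])
    net.check_flow_conservation(rtol=1e-6)
    return net


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def clip_segment_to_box(p0, p1, box) -> float:
    """Length of the line segment p0->p1 inside the half-open box [lo, hi).

    Exact slab clipping; returns 0.0 for segments entirely outside.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    box = np.asarray(box, dtype=float).reshape(2, 3)
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for ax in range(3):
        if abs(d[ax]) < 1e-300:
            if not (box[0, ax] <= p0[ax] < box[1, ax]):
                return 0.0
            continue
        ta = (box[0, ax] - p0[ax]) / d[ax]
        tb = (box[1, ax] - p0[ax]) / d[ax]
        if ta > tb:
            ta, tb = tb, ta
        t0, t1 = max(t0, ta), min(t1, tb)
        if t0 >= t1:
            return 0.0
    return float((t1 - t0) * np.linalg.norm(d))
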