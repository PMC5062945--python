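"""The image-fusion pipeline.

A virtual voxel grid (the "imaging" grid) is superimposed on the tissue.
For every voxel the vascular architecture inside it is reduced to the
effective inputs a functional imaging stack would report — fractional
vascular volume, effective radius, perfusion, volume-weighted SaO2 — and
those are fed to the single-vessel MVIF model to produce MPO2.  The
reference GPO2 is the mean of the lattice LPO2 inside the same voxel.

Effective-input conventions (chosen so a voxel containing exactly one
straight spanning vessel is reproduced exactly):

    fvv    = Σ_i π r_i² len_i(voxel) / V
    rc_eff = L·√(fvv/π)          (single spanning vessel of equal volume)
    F_eff  = Σ_i Q_i·(len_i(voxel)/ℓ_i) / V
    SaO2   = Σ_i SaO2(i)·vol(i) / Σ_i vol(i)
    P_in   = Hill⁻¹(SaO2),  m = H·C'·dS/dP at P_in

with V the tissue volume of the voxel (voxel ∩ domain) and ℓ_i the
crossing length of that volume along vessel i's direction (both equal
L³ and L for a voxel fully inside the tissue), so each vessel's flow is
weighted by the fraction of a full crossing it completes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mvif import MvifInputs, MvifResult, mvif_voxel_average, default_tissue_radius
from .physiology import PhysiologyParams, hill_inverse, hill_saturation, hill_slope_m
from .reference_solver import TissueLattice, average_gpo2
from .vasculature import VesselNetwork, clip_segment_to_box

__all__ = [
    "VoxelGrid",
    "VoxelInputs",
    "OxygenMaps",
    "make_voxel_grid",
    "effective_voxel_inputs",
    "run_fusion",
    "grid_translation_ensemble",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Isotropic half-open voxel grid covering the domain box.

    ``origin`` already includes the random translation ``offset``; voxel i
    spans [origin + i·L, origin + (i+1)·L) per axis and the index range is
    chosen so every point of the domain falls in some voxel.
    """

    origin: np.ndarray  # (3,) µm
    edge: float  # L, µm
    dims: tuple[int, int, int]
    offset: np.ndarray  # (3,) µm, the translation applied

    def voxel_box(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        lo = self.origin + idx * self.edge
        return np.array([lo, lo + self.edge])

    def voxel_index(self, xyz: np.ndarray) -> np.ndarray:
        """(N, 3) integer voxel indices of physical points (half-open rule)."""
        return np.floor((np.asarray(xyz) - self.origin) / self.edge).astype(int)

    def centers(self) -> np.ndarray:
        axes = [self.origin[ax] + (np.arange(self.dims[ax]) + 0.5) * self.edge
                for ax in range(3)]
        g = np.meshgrid(*axes, indexing="ij")
        return np.stack([a.ravel() for a in g], axis=1)


@dataclass(frozen=True)
class VoxelInputs:
    fvv: float
    rc_eff: float  # µm
    F_eff: float  # 1/s
    sao2_in: float
    P_in: float  # mmHg
    m: float
    valid: bool

    @staticmethod
    def invalid() -> "VoxelInputs":
        nan = float("nan")
        return VoxelInputs(0.0, nan, nan, nan, nan, nan, valid=False)


@dataclass
class OxygenMaps:
    grid: VoxelGrid
    gpo2: np.ndarray
    mpo2: np.ndarray
    valid: np.ndarray  # both maps defined (vessel present and lattice points present)
    inputs: dict[tuple[int, int, int], VoxelInputs] = field(default_factory=dict)
    results: dict[tuple[int, int, int], MvifResult] = field(default_factory=dict)

    def scatter_table(self, offset_id: int = 0) -> pd.DataFrame:
        """Long-format per-voxel table of inputs and both pO2 estimates."""
        rows = []
        for (i, j, k), vi in self.inputs.items():
            res = self.results.get((i, j, k))
            rows.append(dict(
                ix=i, iy=j, iz=k, offset_id=offset_id,
                fvv=vi.fvv, rc_eff=vi.rc_eff, F=vi.F_eff, sao2=vi.sao2_in,
                P_in=vi.P_in, m=vi.m,
                gpo2=self.gpo2[i, j, k], mpo2=self.mpo2[i, j, k],
                valid=bool(self.valid[i, j, k]),
                clamped=bool(res.clamped) if res else False,
            ))
        return pd.DataFrame(rows)


def make_voxel_grid(domain_box, L: float, offset=(0.0, 0.0, 0.0)) -> VoxelGrid:
    """Grid of edge ``L`` covering ``domain_box``, translated by ``offset``.

    Offsets must stay below half a voxel per axis (the grid-translation
    protocol); the grid is extended so translated voxels still cover the
    whole domain.
    """
    if L <= 0:
        raise ValueError("voxel edge must be positive")
    box = np.asarray(domain_box, dtype=float).reshape(2, 3)
    offset = np.asarray(offset, dtype=float)
    if np.any(np.abs(offset) >= L / 2):
        raise ValueError(f"|offset| must be < L/2 = {L / 2}")
    lo, hi = box
    # anchor at lo + offset, then slide back whole voxels to cover the domain
    first = np.floor((lo - (lo + offset)) / L).astype(int)
    origin = lo + offset + first * L
    dims = tuple(int(np.ceil((hi[ax] - origin[ax]) / L - 1e-12)) for ax in range(3))
    return VoxelGrid(origin=origin, edge=L, dims=dims, offset=offset)


def _segment_sao2_in_voxel(net: VesselNetwork, seg_id: int, box: np.ndarray,
                           params: PhysiologyParams) -> float | None:
    """Mean SaO2 of a segment's subsegment midpoints inside the voxel.

    Falls back to the whole-segment mean when no midpoint lands inside,
    and to None when the solver left no profile for the segment.
    """
    profile = net.subsegment_po2.get(seg_id)
    if not profile:
        return None
    inside = [po2 for (mid, _len, po2) in profile
              if np.all(mid >= box[0]) and np.all(mid < box[1]) and np.isfinite(po2)]
    pool = inside if inside else [po2 for (_m, _l, po2) in profile if np.isfinite(po2)]
    if not pool:
        return None
    return float(np.mean([hill_saturation(p, params) for p in pool]))


def effective_voxel_inputs(net: VesselNetwork, voxel_box, L: float,
                           params: PhysiologyParams,
                           domain_box=None) -> VoxelInputs:
    """Reduce the vasculature inside one voxel to MVIF inputs.

    Voxels partially outside the tissue domain are normalized by the
    tissue volume actually inside (voxel ∩ domain), so vascular density
    and perfusion stay local densities rather than being diluted by
    empty space beyond the tissue boundary.
    """
    box = np.asarray(voxel_box, dtype=float).reshape(2, 3)
    tissue_fraction = 1.0
    if domain_box is not None:
        dom = np.asarray(domain_box, dtype=float).reshape(2, 3)
        inter_lo = np.maximum(box[0], dom[0])
        inter_hi = np.minimum(box[1], dom[1])
        if np.any(inter_hi <= inter_lo):
            return VoxelInputs.invalid()
        box = np.array([inter_lo, inter_hi])
        tissue_fraction = float(np.prod(inter_hi - inter_lo)) / L**3
    vol_total = 0.0
    flow_len = 0.0
    sao2_weighted = 0.0
    sao2_norm = 0.0
    ext = box[1] - box[0]
    for seg in net.segments:
        p0, p1 = net.segment_endpoints(seg)
        length_in = clip_segment_to_box(p0, p1, box)
        if length_in <= 0:
            continue
        vol = np.pi * seg.radius**2 * length_in
        vol_total += vol
        # crossing length of the box along this vessel's direction: the
        # denominator that makes a single spanning vessel exact (L for a
        # full voxel, the slab thickness for a boundary-clipped one)
        u = np.abs(p1 - p0) / np.linalg.norm(p1 - p0)
        crossing = float(np.min(np.where(u > 1e-12, ext / np.maximum(u, 1e-12), np.inf)))
        flow_len += abs(seg.flow) * length_in / min(crossing, np.linalg.norm(ext))
        sao2 = _segment_sao2_in_voxel(net, seg.id, box, params)
        if sao2 is not None:
            sao2_weighted += sao2 * vol
            sao2_norm += vol
    V = L**3 * tissue_fraction
    fvv = vol_total / V
    if fvv <= 0 or sao2_norm <= 0:
        return VoxelInputs.invalid()
    sao2_in = min(sao2_weighted / sao2_norm, 1.0 - 1e-12)
    P_in = hill_inverse(sao2_in, params)
    rc_eff = L * np.sqrt(fvv / np.pi)
    F_eff = flow_len / V
    m = hill_slope_m(max(P_in, 1e-9), params)
    return VoxelInputs(fvv=fvv, rc_eff=rc_eff, F_eff=F_eff, sao2_in=sao2_in,
                       P_in=P_in, m=m, valid=True)


def mvif_from_voxel(vi: VoxelInputs, L: float, params: PhysiologyParams,
                    mm_coupling: bool = True, M: float | None = None) -> MvifResult:
    """Run the MVIF voxel model on one voxel's effective inputs."""
    from .mvif import invalid_result

    if not vi.valid or vi.F_eff <= 0:
        return invalid_result()
    rT = default_tissue_radius(L)
    rc = min(vi.rc_eff, 0.999 * rT)  # fvv -> 1 degenerates to rc = rT
    inputs = MvifInputs(P_in=vi.P_in, F=vi.F_eff, rc=rc, L=L, m=vi.m,
                        params=params, M=M, mm_coupling=mm_coupling)
    return mvif_voxel_average(inputs)


def run_fusion(net: VesselNetwork, lattice: TissueLattice, grid: VoxelGrid,
               params: PhysiologyParams, mm_coupling: bool = True) -> OxygenMaps:
    """Compute aligned MPO2 and GPO2 maps on ``grid``.

    MPO2 is computed for every voxel with vasculature; GPO2 for every voxel
    containing lattice points; the joint validity mask marks voxels where
    both are defined.  Deterministic given its inputs.
    """
    gpo2, g_valid = average_gpo2(lattice, grid)
    mpo2 = np.full(grid.dims, np.nan)
    m_valid = np.zeros(grid.dims, dtype=bool)
    maps = OxygenMaps(grid=grid, gpo2=gpo2, mpo2=mpo2,
                      valid=np.zeros(grid.dims, dtype=bool))
    for i in range(grid.dims[0]):
        for j in range(grid.dims[1]):
            for k in range(grid.dims[2]):
                box = grid.voxel_box((i, j, k))
                vi = effective_voxel_inputs(net, box, grid.edge, params,
                                            domain_box=net.domain_box)
                maps.inputs[(i, j, k)] = vi
                if not vi.valid:
                    continue
                res = mvif_from_voxel(vi, grid.edge, params, mm_coupling=mm_coupling)
                maps.results[(i, j, k)] = res
                if res.valid:
                    mpo2[i, j, k] = res.mpo2
                    m_valid[i, j, k] = True
    maps.valid = m_valid & g_valid
    if not maps.valid.any():
        import warnings

        warnings.warn("fusion produced no valid voxels", stacklevel=2)
    return maps


def grid_translation_ensemble(net: VesselNetwork, lattice: TissueLattice,
                              L: float, params: PhysiologyParams,
                              n_offsets: int = 1, seed: int = 0,
                              mm_coupling: bool = True) -> pd.DataFrame:
    """Pooled scatter table over randomly translated grids.

    The first ensemble member is the untranslated grid; the remaining
    offsets are drawn uniformly from (−L/2, L/2)³ with a seeded RNG.
    """
    if n_offsets < 1:
        raise ValueError("n_offsets must be >= 1")
    rng = np.random.default_rng(seed)
    tables = []
    for oid in range(n_offsets):
        if oid == 0:
            offset = np.zeros(3)
        else:
            offset = rng.uniform(-L / 2, L / 2, size=3) * 0.999
        grid = make_voxel_grid(net.domain_box, L, offset)
        maps = run_fusion(net, lattice, grid, params, mm_coupling=mm_coupling)
        tables.append(maps.scatter_table(offset_id=oid))
    return pd.concat(tables, ignore_index=True)
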