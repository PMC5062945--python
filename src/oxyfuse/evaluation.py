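"""Validation statistics and perturbation studies.

Everything here consumes the per-voxel scatter tables / maps produced by
the fusion stage: MPO2-vs-GPO2 ordinary least squares, hypoxic fractions
and their threshold-ladder regression, the six-neighbor correction for
small voxels, one-at-a-time sensitivity scans, and Gaussian
measurement-error propagation with per-voxel replicate streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fusion import VoxelInputs, mvif_from_voxel
from .physiology import (
    PhysiologyParams,
    FWHM_PER_SIGMA,
    hill_inverse,
    hill_slope_m,
)

__all__ = [
    "RegressionResult",
    "linear_regression",
    "hypoxic_fraction",
    "hf_correlation",
    "nearest_neighbor_correction",
    "SensitivityTable",
    "sensitivity_scan",
    "ErrorPropagationResult",
    "gaussian_error_propagation",
    "TUMOR_HF_THRESHOLDS",
    "BRAIN_HF_THRESHOLDS",
]

#: Hypoxic-fraction threshold ladders, mmHg: 2.5-15 in 2.5 steps for tumor,
#: 16-22 in 2 steps for well-oxygenated brain tissue.
TUMOR_HF_THRESHOLDS = tuple(np.arange(2.5, 15.0 + 1e-9, 2.5))
BRAIN_HF_THRESHOLDS = tuple(np.arange(16.0, 22.0 + 1e-9, 2.0))


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float  # mmHg
    r_squared: float
    pearson_r: float
    p_value: float
    n_points: int


def linear_regression(x, y=None) -> RegressionResult:
    """OLS of MPO2 on GPO2 (y on x) with two-sided p for Pearson R.

    Accepts either two arrays or a DataFrame with ``gpo2``/``mpo2``
    columns (rows with either value missing are dropped).
    """
    if y is None:
        df = x
        keep = df["valid"] if "valid" in df else np.isfinite(df["gpo2"]) & np.isfinite(df["mpo2"])
        x = df.loc[keep, "gpo2"].to_numpy(dtype=float)
        y = df.loc[keep, "mpo2"].to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need >= 3 paired points, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the reference values")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2), pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue), n_points=len(x),
    )


def hypoxic_fraction(values, threshold: float, mask=None) -> float:
    """Fraction of valid voxels with pO2 strictly below ``threshold``.

    Zero-clamped voxels count as hypoxic for any positive threshold.
    """
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isfinite(values)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(values)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no valid voxels for the hypoxic fraction")
    return float(np.count_nonzero(values[mask] < threshold) / n)


def hf_correlation(mpo2, gpo2, thresholds, mask=None) -> RegressionResult:
    """Regression of HF(MPO2) on HF(GPO2) across a threshold ladder."""
    thresholds = np.asarray(thresholds, dtype=float)
    if len(thresholds) < 3:
        raise ValueError("need >= 3 thresholds for the HF regression")
    hf_m = [hypoxic_fraction(mpo2, t, mask) for t in thresholds]
    hf_g = [hypoxic_fraction(gpo2, t, mask) for t in thresholds]
    if np.ptp(hf_g) == 0 and np.ptp(hf_m) == 0:
        raise ValueError("hypoxic fractions are constant across the ladder")
    return linear_regression(np.asarray(hf_g), np.asarray(hf_m))


def nearest_neighbor_correction(values, valid=None, mode: str = "replace"):
    """Six-neighbor smoothing of a 3-D voxel map.

    ``replace``: each voxel becomes the mean of its existing face-adjacent
    valid neighbors (voxels with no valid neighbor keep their value).
    ``include-self``: the voxel's own value enters the average too.
    Invalid voxels gain a value when at least one valid neighbor exists.
    Returns ``(corrected, new_valid)``.
    """
    if mode not in ("replace", "include-self"):
        raise ValueError("mode must be 'replace' or 'include-self'")
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    valid = np.asarray(valid, dtype=bool)
    filled = np.where(valid, values, 0.0)
    nsum = np.zeros_like(filled)
    ncount = np.zeros_like(filled)
    for ax in range(3):
        for shift in (1, -1):
            nsum += _shifted(filled, ax, shift)
            ncount += _shifted(valid.astype(float), ax, shift)
    if mode == "include-self":
        nsum += filled
        ncount += valid
    have_neighbors = ncount > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        neighbor_mean = np.where(have_neighbors, nsum / np.maximum(ncount, 1), np.nan)
    corrected = np.where(have_neighbors, neighbor_mean, values)
    new_valid = valid | have_neighbors
    corrected = np.where(new_valid, corrected, np.nan)
    return corrected, new_valid


def _shifted(a: np.ndarray, axis: int, shift: int) -> np.ndarray:
    out = np.zeros_like(a)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if shift > 0:
        src[axis], dst[axis] = slice(1, None), slice(None, -1)
    else:
        src[axis], dst[axis] = slice(None, -1), slice(1, None)
    out[tuple(dst)] = a[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# sensitivity scan
# ---------------------------------------------------------------------------

SENSITIVITY_INPUTS = ("rc", "F", "M0", "SaO2", "CtHb")
SENSITIVITY_FACTORS = (0.8, 0.9, 1.1, 1.2)


@dataclass
class SensitivityTable:
    rows: pd.DataFrame  # columns: input, factor, percent_deviation

    def deviation(self, name: str, factor: float) -> float:
        m = (self.rows["input"] == name) & np.isclose(self.rows["factor"], factor)
        return float(self.rows.loc[m, "percent_deviation"].iloc[0])

    def mean_absolute(self, name: str) -> float:
        m = self.rows["input"] == name
        return float(self.rows.loc[m, "percent_deviation"].abs().mean())


def _perturbed_inputs(vi: VoxelInputs, name: str, factor: float,
                      params: PhysiologyParams
                      ) -> tuple[VoxelInputs, PhysiologyParams]:
    """One-at-a-time perturbation of a voxel's effective inputs."""
    if name == "rc":
        return (VoxelInputs(vi.fvv * factor**2, vi.rc_eff * factor, vi.F_eff,
                            vi.sao2_in, vi.P_in, vi.m, vi.valid), params)
    if name == "F":
        return (VoxelInputs(vi.fvv, vi.rc_eff, vi.F_eff * factor,
                            vi.sao2_in, vi.P_in, vi.m, vi.valid), params)
    if name == "M0":
        return vi, params.with_(M0=params.M0 * factor)
    if name == "SaO2":
        # re-clipped below full saturation: the inverse Hill relation
        # diverges at S = 1, so the cap is the upper end of arterial
        # saturations rather than the mathematical limit
        sao2 = min(vi.sao2_in * factor, 0.99)
        P_in = hill_inverse(sao2, params)
        m = hill_slope_m(max(P_in, 1e-9), params)
        return (VoxelInputs(vi.fvv, vi.rc_eff, vi.F_eff, sao2, P_in, m,
                            vi.valid), params)
    if name == "CtHb":
        params2 = params.with_(C_prime=params.C_prime * factor)
        m = hill_slope_m(max(vi.P_in, 1e-9), params2)
        return (VoxelInputs(vi.fvv, vi.rc_eff, vi.F_eff, vi.sao2_in, vi.P_in,
                            m, vi.valid), params2)
    raise ValueError(f"unknown sensitivity input {name!r}")


def sensitivity_scan(voxel_inputs: list[VoxelInputs], L: float,
                     params: PhysiologyParams,
                     inputs=SENSITIVITY_INPUTS,
                     factors=SENSITIVITY_FACTORS,
                     mm_coupling: bool = False,
                     baseline_floor: float = 1.0) -> SensitivityTable:
    """Percent change of the mean MPO2 when one input is scaled.

    deviation(input, factor) = 100·(⟨MPO2⟩_factor − ⟨MPO2⟩_ref)/⟨MPO2⟩_ref
    over valid voxels whose baseline MPO2 exceeds ``baseline_floor``
    (mmHg): a relative deviation is not meaningful for voxels the model
    clamps at zero, and including them lets the clamp — not the input —
    dominate the percentage.

    The scan treats the consumption rate as the constant M of the voxel
    equation (no Michaelis-Menten feedback): M0 is one of the inputs being
    varied, and coupling it to the resulting MPO2 would partially cancel
    the very response being measured.
    """
    valid = [vi for vi in voxel_inputs if vi.valid and vi.F_eff > 0]
    if not valid:
        raise ValueError("no valid voxels in the baseline run")
    base = [mvif_from_voxel(vi, L, params, mm_coupling).mpo2 for vi in valid]
    valid = [vi for vi, b in zip(valid, base) if b >= baseline_floor]
    if not valid:
        raise ValueError(f"no voxels with baseline MPO2 >= {baseline_floor} mmHg")
    ref = np.mean([b for b in base if b >= baseline_floor])
    rows = []
    for name in inputs:
        for factor in factors:
            vals = []
            for vi in valid:
                vi2, params2 = _perturbed_inputs(vi, name, factor, params)
                vals.append(mvif_from_voxel(vi2, L, params2, mm_coupling).mpo2)
            dev = 100.0 * (np.mean(vals) - ref) / ref
            rows.append(dict(input=name, factor=factor, percent_deviation=dev))
    return SensitivityTable(rows=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Gaussian measurement-error propagation
# ---------------------------------------------------------------------------

@dataclass
class ErrorPropagationResult:
    per_voxel: pd.DataFrame  # columns: voxel, mean, sd, se, cv
    average_cv: float  # mean CV over voxels, as a fraction
    n_replicates: int
    seed: int
    target: str


def gaussian_error_propagation(voxel_inputs: list[VoxelInputs], L: float,
                               params: PhysiologyParams, target: str = "F",
                               fwhm_fraction: float = 0.20,
                               n_replicates: int = 10, seed: int = 0,
                               mm_coupling: bool = True,
                               max_redraws: int = 100) -> ErrorPropagationResult:
    """Monte-Carlo propagation of imaging noise on F or fvv into MPO2.

    Each voxel's target input is resampled ``n_replicates`` times from
    Normal(value, σ) with σ = fwhm_fraction·value/√(8·ln 2) (FWHM equal to
    the stated fraction of the value), non-positive draws redrawn.  Every
    voxel gets an independent, order-insensitive substream derived from
    (seed, voxel index).  Reports per-voxel mean/SD/SE/CV and the average
    CV over voxels whose baseline MPO2 is positive.
    """
    if target not in ("F", "fvv"):
        raise ValueError("target must be 'F' or 'fvv'")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    valid = [(i, vi) for i, vi in enumerate(voxel_inputs) if vi.valid and vi.F_eff > 0]
    if not valid:
        raise ValueError("no valid voxels")
    rows = []
    for vox_idx, vi in valid:
        base = vi.F_eff if target == "F" else vi.fvv
        sigma = fwhm_fraction * base / FWHM_PER_SIGMA
        rng = np.random.default_rng([seed, vox_idx])
        replicates = []
        for _rep in range(n_replicates):
            value = base if sigma == 0 else _positive_normal(rng, base, sigma, max_redraws)
            if target == "F":
                vi2 = VoxelInputs(vi.fvv, vi.rc_eff, value, vi.sao2_in,
                                  vi.P_in, vi.m, vi.valid)
            else:
                rc = L * np.sqrt(value / np.pi)
                vi2 = VoxelInputs(value, rc, vi.F_eff, vi.sao2_in,
                                  vi.P_in, vi.m, vi.valid)
            replicates.append(mvif_from_voxel(vi2, L, params, mm_coupling).mpo2)
        replicates = np.asarray(replicates)
        mean = float(replicates.mean())
        sd = float(replicates.std(ddof=1))
        rows.append(dict(voxel=vox_idx, mean=mean, sd=sd,
                         se=sd / np.sqrt(n_replicates),
                         cv=sd / mean if mean > 0 else np.nan))
    per_voxel = pd.DataFrame(rows)
    usable = per_voxel["cv"].dropna()
    return ErrorPropagationResult(
        per_voxel=per_voxel,
        average_cv=float(usable.mean()) if len(usable) else float("nan"),
        n_replicates=n_replicates, seed=seed, target=target,
    )


def _positive_normal(rng: np.random.Generator, mean: float, sigma: float,
                     max_redraws: int) -> float:
    for _ in range(max_redraws):
        draw = rng.normal(mean, sigma)
        if draw > 0:
            return float(draw)
    raise RuntimeError(
        f"could not draw a positive value from N({mean}, {sigma}) "
        f"in {max_redraws} attempts")
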