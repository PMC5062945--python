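"""Validation statistics: regression, hypoxic fractions, NN correction,
sensitivity scan, Gaussian error propagation."""

import numpy as np
import pytest

from oxyfuse.evaluation import (
    BRAIN_HF_THRESHOLDS,
    TUMOR_HF_THRESHOLDS,
    gaussian_error_propagation,
    hf_correlation,
    hypoxic_fraction,
    linear_regression,
    nearest_neighbor_correction,
    sensitivity_scan,
)
from oxyfuse.fusion import VoxelInputs
from oxyfuse.physiology import FWHM_PER_SIGMA, hill_inverse, hill_slope_m, tumor_params

P = tumor_params()


def test_regression_identity_and_affine():
    x = np.linspace(1, 40, 25)
    r = linear_regression(x, x)
    assert (r.slope, r.intercept, r.r_squared) == pytest.approx((1.0, 0.0, 1.0))
    r2 = linear_regression(x, 2 * x + 3)
    assert (r2.slope, r2.intercept, r2.r_squared) == pytest.approx((2.0, 3.0, 1.0))
    assert r2.r_squared == pytest.approx(r2.pearson_r**2, abs=1e-12)


def test_regression_preconditions():
    with pytest.raises(ValueError, match="3 paired"):
        linear_regression([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="variance"):
        linear_regression([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])


def test_hypoxic_fraction_examples():
    vals = np.array([1.0, 3.0, 6.0, 12.0])
    assert hypoxic_fraction(vals, 5.0) == 0.5
    assert hypoxic_fraction(vals, 0.5) == 0.0
    assert hypoxic_fraction(vals, 100.0) == 1.0
    with pytest.raises(ValueError):
        hypoxic_fraction(vals, 5.0, mask=np.zeros(4, bool))


@pytest.mark.parametrize("ladder", [TUMOR_HF_THRESHOLDS, BRAIN_HF_THRESHOLDS])
def test_hypoxic_fraction_monotone_over_ladder(ladder):
    rng = np.random.default_rng(0)
    vals = rng.uniform(0, 30, 500)
    hfs = [hypoxic_fraction(vals, t) for t in ladder]
    assert all(a <= b for a, b in zip(hfs, hfs[1:]))
    assert all(0.0 <= h <= 1.0 for h in hfs)


def test_hf_regression_identity_and_shift():
    rng = np.random.default_rng(1)
    gpo2 = rng.uniform(0, 25, 400)
    r = hf_correlation(gpo2, gpo2, TUMOR_HF_THRESHOLDS)
    assert (r.slope, r.r_squared) == pytest.approx((1.0, 1.0))
    # a global −2 mmHg shift keeps slope near 1 with a positive HF offset
    r2 = hf_correlation(gpo2 - 2.0, gpo2, TUMOR_HF_THRESHOLDS)
    assert r2.slope == pytest.approx(1.0, abs=0.25)
    assert r2.intercept > 0
    with pytest.raises(ValueError):
        hf_correlation(gpo2, gpo2, [5.0])


def test_nearest_neighbor_modes():
    m = np.full((3, 3, 3), 7.0)
    for mode in ("replace", "include-self"):
        out, valid = nearest_neighbor_correction(m, mode=mode)
        np.testing.assert_allclose(out, 7.0)
        assert valid.all()
    m2 = np.full((3, 3, 3), 12.0)
    m2[1, 1, 1] = 0.0
    out, _ = nearest_neighbor_correction(m2)
    assert out[1, 1, 1] == pytest.approx(12.0)
    # corner voxel averages its three existing neighbors
    m3 = np.zeros((3, 3, 3))
    m3[1, 0, 0] = 3.0
    m3[0, 1, 0] = 6.0
    m3[0, 0, 1] = 9.0
    out3, _ = nearest_neighbor_correction(m3)
    assert out3[0, 0, 0] == pytest.approx(6.0)
    # invalid voxels fill from valid neighbors
    vals = np.full((3, 3, 3), np.nan)
    vals[1, 1, 0] = 10.0
    out4, valid4 = nearest_neighbor_correction(vals)
    assert valid4[1, 1, 1] and out4[1, 1, 1] == pytest.approx(10.0)
    with pytest.raises(ValueError):
        nearest_neighbor_correction(m, mode="bogus")


def _voxel_inputs(sao2=0.85, F=0.01, fvv=0.015, L=150.0):
    rc = L * np.sqrt(fvv / np.pi)
    p_in = hill_inverse(sao2, P)
    return VoxelInputs(fvv=fvv, rc_eff=rc, F_eff=F, sao2_in=sao2, P_in=p_in,
                       m=hill_slope_m(p_in, P), valid=True)


def test_sensitivity_scan_identity_factor_and_signs():
    vis = [_voxel_inputs(sao2=s, F=f) for s, f in
           [(0.80, 0.008), (0.85, 0.012), (0.9, 0.02), (0.75, 0.01)]]
    table = sensitivity_scan(vis, 150.0, P, factors=(0.8, 1.0, 1.2))
    for name in ("rc", "F", "M0", "SaO2", "CtHb"):
        assert table.deviation(name, 1.0) == pytest.approx(0.0, abs=1e-9)
    assert table.deviation("M0", 1.2) < 0
    assert table.deviation("F", 1.2) > 0
    assert table.deviation("SaO2", 1.2) > 0
    assert table.deviation("CtHb", 1.2) > 0


def test_sensitivity_scan_requires_valid_voxels():
    with pytest.raises(ValueError):
        sensitivity_scan([VoxelInputs.invalid()], 150.0, P)


def test_error_propagation_reproducible_and_scaled():
    vis = [_voxel_inputs(sao2=s) for s in (0.8, 0.85, 0.9)]
    a = gaussian_error_propagation(vis, 150.0, P, target="F", seed=7)
    b = gaussian_error_propagation(vis, 150.0, P, target="F", seed=7)
    assert a.per_voxel.equals(b.per_voxel)
    assert np.isfinite(a.average_cv) and a.average_cv >= 0
    zero = gaussian_error_propagation(vis, 150.0, P, target="F",
                                      fwhm_fraction=0.0, seed=7)
    assert zero.average_cv == 0.0
    with pytest.raises(ValueError):
        gaussian_error_propagation(vis, 150.0, P, n_replicates=1)


def test_error_propagation_order_independent():
    """Replicate streams key on the voxel index, not iteration order."""
    vis = [_voxel_inputs(sao2=s) for s in (0.8, 0.85, 0.9)]
    full = gaussian_error_propagation(vis, 150.0, P, target="fvv", seed=3)
    solo = gaussian_error_propagation(
        [VoxelInputs.invalid(), vis[1], VoxelInputs.invalid()], 150.0, P,
        target="fvv", seed=3)
    row_full = full.per_voxel.set_index("voxel").loc[1]
    row_solo = solo.per_voxel.set_index("voxel").loc[1]
    assert row_full["mean"] == pytest.approx(row_solo["mean"])
    assert row_full["cv"] == pytest.approx(row_solo["cv"])


def test_fwhm_sigma_identity():
    assert FWHM_PER_SIGMA == pytest.approx(2.3548, abs=1e-4)
    assert 0.2 / FWHM_PER_SIGMA == pytest.approx(0.0849, abs=1e-4)
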