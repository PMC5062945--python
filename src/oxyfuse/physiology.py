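"""Blood-oxygen relations and unit canonicalization.

All quantities inside the package live in a single canonical unit system:
lengths in µm, time in s, pressures in mmHg, concentrations in µM
(µmol per litre; note 1 µM = 1e-21 mol/µm³, but the µM·µm³ product is used
consistently so the litre never leaks out).

The hemoglobin dissociation curve is the Hill equation

    S(P) = P^n / (P^n + P50^n)

with Hill coefficient ``n`` and half-saturation pressure ``P50``.  Dissolved
(free) oxygen follows Henry's law, ``C_free = P / H`` with ``H`` in mmHg/µM.
Tissue consumption is Michaelis-Menten, ``M(P) = M0 · P / (P + Km)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PhysiologyParams",
    "tumor_params",
    "brain_params",
    "hill_saturation",
    "hill_inverse",
    "hill_slope",
    "hill_slope_m",
    "michaelis_menten_rate",
    "blood_o2_content",
    "blood_po2_from_content",
    "to_canonical_units",
]

#: Molar volume of an ideal gas at standard conditions, cm³ O2 per mol.
#: Used to convert volumetric O2 fractions (cm³O2/cm³) into molar
#: concentrations, the convention of the classic oxygen-transport literature.
MOLAR_VOLUME_STP = 22_400.0

#: FWHM of a Gaussian in units of its standard deviation.
FWHM_PER_SIGMA = float(np.sqrt(8.0 * np.log(2.0)))


@dataclass(frozen=True)
class PhysiologyParams:
    """Physiological constants in canonical units (µm, s, mmHg, µM).

    Attributes
    ----------
    H : float
        Henry constant for plasma, mmHg/µM.
    D : float
        Oxygen diffusion constant in tissue, µm²/s.
    C_prime : float
        O2-binding capacity of saturated hemoglobin per blood volume, µM.
    n_hill : float
        Hill coefficient (dimensionless, >= 1).
    P50 : float
        Half-saturation pressure of hemoglobin, mmHg.
    M0 : float
        Maximum oxygen consumption rate, µM/s.
    Km : float
        Michaelis-Menten half-rate pressure, mmHg.  Not a tabulated value
        in the source datasets this package emulates; 1.0 mmHg is the
        typical choice in the Green's-function oxygen-transport
        literature and is configurable.
    alpha_blood : float | None
        O2 solubility in blood, µM/mmHg.  ``None`` means derive as ``1/H``.
    """

    H: float = 0.74
    D: float = 2000.0
    C_prime: float = 8800.0
    n_hill: float = 3.0
    P50: float = 26.0
    M0: float = 17.857142857142858  # 0.0004 cm³O2/cm³/s in µM/s
    Km: float = 1.0
    alpha_blood: float | None = None

    def __post_init__(self) -> None:
        for name in ("H", "D", "C_prime", "n_hill", "P50", "M0", "Km"):
            v = getattr(self, name)
            if not np.isfinite(v) or (v < 0) or (v == 0 and name not in ("M0", "C_prime")):
                raise ValueError(f"PhysiologyParams.{name} must be positive, got {v!r}")
        if self.n_hill < 1:
            raise ValueError(f"Hill coefficient must be >= 1, got {self.n_hill}")

    @property
    def alpha(self) -> float:
        """Tissue/plasma O2 solubility, µM/mmHg (1/H unless overridden)."""
        return 1.0 / self.H if self.alpha_blood is None else self.alpha_blood

    def with_(self, **kwargs) -> "PhysiologyParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def tumor_params(**overrides) -> PhysiologyParams:
    """Tumor parameter preset (M0 = 0.0004 cm³O2/cm³/s ≈ 17.86 µM/s)."""
    return PhysiologyParams(**overrides)


def brain_params(**overrides) -> PhysiologyParams:
    """Brain (normal tissue) preset: higher metabolic rate, same blood constants."""
    defaults = dict(M0=to_canonical_units(0.0025, "cm3O2/cm3/s"))
    defaults.update(overrides)
    return PhysiologyParams(**defaults)


def hill_saturation(P, params: PhysiologyParams):
    """Hemoglobin saturation S(P) = P^n / (P^n + P50^n); P in mmHg.

    Accepts scalars or arrays; P must be non-negative.
    """
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("hill_saturation requires P >= 0")
    Pn = P**params.n_hill
    out = Pn / (Pn + params.P50**params.n_hill)
    return float(out) if out.ndim == 0 else out


def hill_inverse(S, params: PhysiologyParams):
    """Pressure at saturation S: P = P50 · (S/(1-S))^(1/n).

    S must lie in [0, 1); S = 0 maps to 0 mmHg, S -> 1 diverges.
    """
    S = np.asarray(S, dtype=float)
    if np.any((S < 0) | (S >= 1)):
        raise ValueError("hill_inverse requires 0 <= S < 1 (S=1 is unbounded)")
    out = params.P50 * (S / (1.0 - S)) ** (1.0 / params.n_hill)
    return float(out) if out.ndim == 0 else out


def hill_slope(P, params: PhysiologyParams):
    """dS/dP of the Hill curve, 1/mmHg (P > 0)."""
    P = np.asarray(P, dtype=float)
    if np.any(P <= 0):
        raise ValueError("hill_slope requires P > 0")
    n, P50 = params.n_hill, params.P50
    out = n * P ** (n - 1) * P50**n / (P**n + P50**n) ** 2
    return float(out) if out.ndim == 0 else out


def hill_slope_m(P, params: PhysiologyParams):
    """Dimensionless dissociation slope factor m = H · C' · dS/dP.

    m measures how much bound oxygen hemoglobin releases per unit drop of
    free pO2: the effective oxygen capacity of blood is (1+m) times the
    dissolved capacity.  It appears in the advection term of the voxel
    model as a buffering factor.
    """
    out = params.H * params.C_prime * np.asarray(hill_slope(P, params))
    return float(out) if out.ndim == 0 else out


def michaelis_menten_rate(P, params: PhysiologyParams):
    """O2 consumption M(P) = M0 · P/(P + Km), µM/s; 0 at P=0, -> M0 as P≫Km."""
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("michaelis_menten_rate requires P >= 0")
    out = params.M0 * P / (P + params.Km)
    return float(out) if out.ndim == 0 else out


def blood_o2_content(P, params: PhysiologyParams, saturation=None):
    """Total blood O2 content per volume, µM: free (P/H) + bound (C'·S(P))."""
    P = np.asarray(P, dtype=float)
    S = hill_saturation(P, params) if saturation is None else saturation
    out = P / params.H + params.C_prime * np.asarray(S)
    return float(out) if out.ndim == 0 else out


def blood_po2_from_content(content: float, params: PhysiologyParams) -> float:
    """Invert ``blood_o2_content`` (monotone) for a single content value, µM.

    Contents at or below zero map to 0 mmHg (fully desaturated, no free O2).
    """
    if content <= 0:
        return 0.0
    lo, hi = 0.0, 1.0
    while blood_o2_content(hi, params) < content:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - content beyond physical range
            raise ValueError(f"blood O2 content {content} µM not invertible")
    from scipy.optimize import brentq

    return float(brentq(lambda p: blood_o2_content(p, params) - content, lo, hi, xtol=1e-10))


# unit tag -> factor into canonical units
_UNIT_FACTORS = {
    # identity tags (already canonical)
    "um": 1.0,
    "um2/s": 1.0,
    "mmHg": 1.0,
    "uM": 1.0,
    "uM/s": 1.0,
    "uM/mmHg": 1.0,
    "mmHg/uM": 1.0,
    "um3/s": 1.0,
    "1/s": 1.0,
    # lengths / areas
    "mm": 1e3,
    "cm2/s": 1e8,
    # volumetric O2 rate -> µM/s: (cm³O2/cm³/s) / 22400 cm³/mol = mol/cm³/s,
    # × 1e3 cm³/L = mol/L/s, × 1e6 = µmol/L/s
    "cm3O2/cm3/s": 1e9 / MOLAR_VOLUME_STP,
    # blood O2 solubility µl O2 / (g · mmHg) -> µM/mmHg (blood density ~1 g/cm³):
    # 1e-3 cm³O2/cm³/mmHg / 22400 × 1e9
    "ulO2/g/mmHg": 1e6 / MOLAR_VOLUME_STP,
    # flows
    "nL/min": 1e6 / 60.0,  # 1 nL = 1e6 µm³
    "nL/s": 1e6,
}


def to_canonical_units(value: float, unit: str) -> float:
    """Convert ``value`` carrying ``unit`` into the canonical system.

    Canonical units: µm, s, mmHg, µM (and products thereof).  Volumetric O2
    fractions are converted through the STP molar volume 22,400 cm³/mol.
    Unknown unit tags raise ``ValueError``.
    """
    try:
        factor = _UNIT_FACTORS[unit]
    except KeyError:
        known = ", ".join(sorted(_UNIT_FACTORS))
        raise ValueError(f"unknown unit tag {unit!r}; known tags: {known}") from None
    return float(value) * factor
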