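"""FRET efficiencies, Förster radii, inter-dye distances and interduplex angles.

The junction carries a fluorescein (FAM) donor and a tetramethylrhodamine
(TAMRA) acceptor on the 5' ends of adjacent arms.  Efficiency is estimated by
the (ratio)_A method: the acceptor emission band of the doubly-labeled sample
is integrated once under donor excitation (sensitized + directly excited
acceptor, F_AD) and once under direct acceptor excitation (F_A)::

    (ratio)_A = F_AD / F_A
    E = ((ratio)_A - eps_A(dEx)/eps_A(aEx)) * (1/f_D) * (eps_A(aEx)/eps_D(dEx))

where eps_A and eps_D are acceptor/donor extinction coefficients at the
excitation wavelengths and f_D is the fraction of donor-labeled molecules.
Subtracting eps_A(dEx)/eps_A(aEx) removes the contribution of direct acceptor
excitation at the donor wavelength.

Distances follow from E through the Förster relation E = R0^6/(R0^6 + R^6)
after correcting the observed efficiency for the stacked-conformer
population: only the isoII conformer (fraction ``iso2_fraction``, default
0.77) brings the dyes close enough to transfer, and isoI contributes zero, so
E_corr = E_obs / iso2_fraction.  The interduplex angle between the two
labeled arms is then the law-of-cosines angle opposite the dye-dye distance
``c`` in the triangle with arm lengths ``a = b = arm_length_bp * rise_per_bp``.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .binding_models import TitrationSeries
from .exceptions import (
    AcceptorSignalAbsentError,
    EfficiencyRangeError,
    GeometryError,
    GridMismatchError,
    IncompatibleSpectraError,
    InvalidLabelingFractionError,
    InvalidPhotophysicsError,
)

__all__ = [
    "SpectrumRole",
    "Spectrum",
    "DyePhotophysics",
    "ForsterParams",
    "JunctionGeometry",
    "ratio_a",
    "efficiency_from_ratio_a",
    "ratio_a_from_efficiency",
    "donor_normalize",
    "overlap_integral",
    "forster_radius",
    "efficiency_from_distance",
    "distance_from_efficiency",
    "interduplex_angle",
    "DEFAULT_ACCEPTOR_BAND_NM",
    "FORSTER_PREFACTOR_A6",
]

#: Default acceptor-emission integration band (nm) for (ratio)_A: the TAMRA
#: emission scan range.
DEFAULT_ACCEPTOR_BAND_NM: Tuple[float, float] = (570.0, 700.0)

#: Förster prefactor for R0^6 in Å^6 with J in M^-1 cm^-1 nm^4:
#: R0^6 = FORSTER_PREFACTOR_A6 * kappa^2 * n^-4 * Q_D * J.
FORSTER_PREFACTOR_A6 = 8.79e-5


class SpectrumRole(enum.Enum):
    DONOR_EMISSION = "donor_emission"
    ACCEPTOR_EMISSION = "acceptor_emission"
    ACCEPTOR_EXCITATION = "acceptor_excitation"
    ACCEPTOR_ABSORPTION = "acceptor_absorption"


@dataclass(frozen=True)
class Spectrum:
    """A (wavelength, intensity) series on a strictly increasing nm grid.

    ``intensity`` is in arbitrary units for emission spectra and in
    extinction units (M^-1 cm^-1) for absorption spectra used in overlap
    integrals.
    """

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    role: SpectrumRole = SpectrumRole.DONOR_EMISSION

    def __post_init__(self):
        wl = np.asarray(self.wavelength_nm, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "intensity", it)
        if wl.size == 0:
            raise ValueError("empty spectrum")
        if wl.size != it.size:
            raise ValueError("wavelength and intensity lengths differ")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(it)):
            raise ValueError("intensities must be finite")
        if np.any(it < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def range_nm(self) -> Tuple[float, float]:
        return float(self.wavelength_nm[0]), float(self.wavelength_nm[-1])


@dataclass(frozen=True)
class DyePhotophysics:
    """Extinction coefficients and labeling stoichiometry of the dye pair.

    Defaults are the TAMRA/FAM values at 555/494 nm excitation; the acceptor
    extinction at the *donor* excitation wavelength is not a catalogue number
    and must be supplied (directly, or measured from an acceptor-only
    spectrum pair via :func:`ratio_a`).
    """

    eps_acceptor_at_acceptor_ex: float = 89_100.0  # M^-1 cm^-1, TAMRA @ 555 nm
    eps_donor_at_donor_ex: float = 78_000.0        # M^-1 cm^-1, FAM @ 494 nm
    eps_acceptor_at_donor_ex: float = 0.0          # M^-1 cm^-1, TAMRA @ 494 nm
    donor_quantum_yield: float = 1.0
    fraction_donor_labeled: float = 1.0

    def __post_init__(self):
        if self.eps_acceptor_at_acceptor_ex <= 0 or self.eps_donor_at_donor_ex <= 0:
            raise InvalidPhotophysicsError("extinction coefficients must be > 0")
        if self.eps_acceptor_at_donor_ex < 0:
            raise InvalidPhotophysicsError("extinction coefficients must be >= 0")
        if not (0 < self.donor_quantum_yield <= 1):
            raise InvalidPhotophysicsError("quantum yield must be in (0, 1]")
        if not (0 < self.fraction_donor_labeled <= 1):
            raise InvalidLabelingFractionError(
                "invalid labeling fraction: f_D must be in (0, 1]"
            )


@dataclass(frozen=True)
class ForsterParams:
    """Inputs of the Förster radius: R0^6 ∝ kappa^2 n^-4 Q_D J."""

    overlap_integral_J: float               # M^-1 cm^-1 nm^4
    donor_quantum_yield: float
    kappa_squared: float = 2.0 / 3.0        # isotropic dynamic averaging
    refractive_index: float = 1.4           # aqueous biomolecular medium

    def __post_init__(self):
        if self.overlap_integral_J < 0:
            raise InvalidPhotophysicsError("invalid photophysics: J must be >= 0")
        if not (0 < self.donor_quantum_yield <= 1):
            raise InvalidPhotophysicsError("quantum yield must be in (0, 1]")
        if self.kappa_squared <= 0 or self.refractive_index <= 0:
            raise InvalidPhotophysicsError("kappa^2 and n must be positive")


@dataclass(frozen=True)
class JunctionGeometry:
    """Arm geometry for the law-of-cosines interduplex angle.

    Arms are modeled as straight B-DNA helices: ``a = b = arm_length_bp *
    rise_per_bp``.  Dye linkers (~8 Å offsets off the helix axis) are not
    modeled; this is a known systematic on the absolute angle.
    """

    arm_length_bp: int = 17
    rise_per_bp_A: float = 3.4
    iso2_fraction: float = 0.77

    def __post_init__(self):
        if self.arm_length_bp <= 0 or self.rise_per_bp_A <= 0:
            raise GeometryError("arm length and rise must be positive")
        if not (0 < self.iso2_fraction <= 1):
            raise GeometryError("iso2_fraction must be in (0, 1]")

    @property
    def arm_length_A(self) -> float:
        return self.arm_length_bp * self.rise_per_bp_A


# --- (ratio)_A and efficiency ----------------------------------------------

def _band_integral(spec: Spectrum, band: Tuple[float, float]) -> float:
    """Trapezoidal integral of a spectrum over ``band`` (nm).

    The spectrum's own grid points inside the band are used, with the band
    edges added by linear interpolation.
    """
    lo, hi = float(band[0]), float(band[1])
    if hi <= lo:
        raise ValueError("band must satisfy lo < hi")
    lo_s, hi_s = spec.range_nm
    if lo < lo_s or hi > hi_s:
        raise IncompatibleSpectraError(
            f"incompatible spectra: band [{lo}, {hi}] nm not covered by "
            f"spectrum range [{lo_s}, {hi_s}] nm"
        )
    wl = spec.wavelength_nm
    inner = wl[(wl > lo) & (wl < hi)]
    grid = np.concatenate(([lo], inner, [hi]))
    vals = np.interp(grid, wl, spec.intensity)
    return float(np.trapezoid(vals, grid))


def ratio_a(
    spec_AD: Spectrum,
    spec_A: Spectrum,
    band: Tuple[float, float] = DEFAULT_ACCEPTOR_BAND_NM,
) -> float:
    """(ratio)_A: integrated acceptor-band intensity, donor-excited over
    acceptor-excited.

    Both acceptor-emission spectra come from the same doubly-labeled sample;
    ``spec_AD`` was recorded with donor excitation, ``spec_A`` with direct
    acceptor excitation.
    """
    num = _band_integral(spec_AD, band)
    den = _band_integral(spec_A, band)
    if den <= 0:
        raise AcceptorSignalAbsentError(
            "acceptor signal absent: direct-excitation band integrates to <= 0"
        )
    return num / den


def efficiency_from_ratio_a(r: float, dyes: DyePhotophysics) -> float:
    """FRET efficiency from (ratio)_A.

    ``E = (r - eps_A(dEx)/eps_A(aEx)) * (1/f_D) * (eps_A(aEx)/eps_D(dEx))``.
    May be slightly negative for noisy ``r``; no clamping is applied here.
    """
    if r < 0:
        raise ValueError("(ratio)_A must be >= 0")
    direct = dyes.eps_acceptor_at_donor_ex / dyes.eps_acceptor_at_acceptor_ex
    scale = dyes.eps_acceptor_at_acceptor_ex / (
        dyes.fraction_donor_labeled * dyes.eps_donor_at_donor_ex
    )
    return (r - direct) * scale


def ratio_a_from_efficiency(E: float, dyes: DyePhotophysics) -> float:
    """Inverse of :func:`efficiency_from_ratio_a` (exact affine inverse)."""
    direct = dyes.eps_acceptor_at_donor_ex / dyes.eps_acceptor_at_acceptor_ex
    scale = dyes.eps_acceptor_at_acceptor_ex / (
        dyes.fraction_donor_labeled * dyes.eps_donor_at_donor_ex
    )
    return E / scale + direct


def donor_normalize(
    series: TitrationSeries, donor_only_series: TitrationSeries
) -> TitrationSeries:
    """Correct a (ratio)_A titration for donor quenching/photobleaching.

    Each value is divided by the donor-only intensity at the same titration
    point *relative to its initial value*, so a donor-only channel constant
    over the titration leaves the series unchanged.
    """
    if len(series) != len(donor_only_series) or not np.allclose(
        series.concentration_M, donor_only_series.concentration_M,
        rtol=1e-12, atol=0.0,
    ):
        raise GridMismatchError("grid mismatch between titration and donor-only series")
    ref = donor_only_series.signal
    if ref[0] == 0 or np.any(ref == 0):
        raise ValueError("donor-only intensities must be nonzero")
    corrected = series.signal / (ref / ref[0])
    return TitrationSeries(
        concentration_M=series.concentration_M.copy(),
        signal=corrected,
        signal_sd=None if series.signal_sd is None
        else series.signal_sd / (ref / ref[0]),
        ion=series.ion,
        temperature_K=series.temperature_K,
    )


# --- Förster radius ---------------------------------------------------------

def overlap_integral(donor_em: Spectrum, acceptor_abs: Spectrum) -> float:
    """Spectral overlap J = ∫ F_D(λ) ε_A(λ) λ^4 dλ / ∫ F_D(λ) dλ.

    ``donor_em`` is an emission spectrum in arbitrary units (normalized to
    unit area internally); ``acceptor_abs`` must be on an extinction scale
    (M^-1 cm^-1).  Trapezoidal quadrature on the intersection of the two
    ranges, after linear interpolation onto the union of grid points (i.e.
    locally the finer of the two grids).  Returns J in M^-1 cm^-1 nm^4;
    returns 0 with a warning when the ranges do not overlap.
    """
    lo = max(donor_em.range_nm[0], acceptor_abs.range_nm[0])
    hi = min(donor_em.range_nm[1], acceptor_abs.range_nm[1])
    if hi <= lo:
        warnings.warn("no spectral overlap between donor emission and "
                      "acceptor absorption; J = 0", stacklevel=2)
        return 0.0
    denom = float(np.trapezoid(donor_em.intensity, donor_em.wavelength_nm))
    if denom <= 0:
        raise ValueError("donor emission integrates to zero")
    grid = np.union1d(donor_em.wavelength_nm, acceptor_abs.wavelength_nm)
    grid = np.concatenate(([lo], grid[(grid > lo) & (grid < hi)], [hi]))
    fd = np.interp(grid, donor_em.wavelength_nm, donor_em.intensity)
    eps = np.interp(grid, acceptor_abs.wavelength_nm, acceptor_abs.intensity)
    num = float(np.trapezoid(fd * eps * grid**4, grid))
    return num / denom


def forster_radius(fp: ForsterParams) -> float:
    """Förster radius in Å: R0 = (8.79e-5 κ² n⁻⁴ Q_D J)^(1/6)."""
    if fp.overlap_integral_J <= 0:
        raise InvalidPhotophysicsError("invalid photophysics: J must be > 0")
    r0_6 = (
        FORSTER_PREFACTOR_A6
        * fp.kappa_squared
        * fp.refractive_index ** -4
        * fp.donor_quantum_yield
        * fp.overlap_integral_J
    )
    return float(r0_6 ** (1.0 / 6.0))


# --- distance and angle geometry -------------------------------------------

def efficiency_from_distance(R: float, R0: float, iso2_fraction: float = 0.77) -> float:
    """Observed (population-weighted) efficiency at dye separation R (Å)."""
    if R <= 0 or R0 <= 0:
        raise ValueError("distances must be positive")
    return iso2_fraction * R0**6 / (R0**6 + R**6)


def distance_from_efficiency(
    E_obs: float, R0: float, iso2_fraction: float = 0.77, clamp: bool = False
) -> float:
    """Dye-dye distance (Å) from observed efficiency.

    The observed efficiency is first corrected for the stacked-conformer
    population (isoI transfers nothing): ``E_corr = E_obs / iso2_fraction``,
    then inverted through ``R = R0 * (1/E_corr - 1)**(1/6)``.

    With ``clamp=True``, noisy efficiencies outside the invertible range are
    clipped just inside (0, iso2_fraction) instead of raising.
    """
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    if not (0 < iso2_fraction <= 1):
        raise ValueError("iso2_fraction must be in (0, 1]")
    if clamp:
        eps = 1e-6
        E_obs = float(np.clip(E_obs, eps * iso2_fraction, (1 - eps) * iso2_fraction))
    e_corr = E_obs / iso2_fraction
    if not (0.0 < e_corr < 1.0):
        raise EfficiencyRangeError(
            f"efficiency out of invertible range: E_obs/iso2_fraction = {e_corr:.4g}"
        )
    return float(R0 * (1.0 / e_corr - 1.0) ** (1.0 / 6.0))


def interduplex_angle(c_A: float, geom: JunctionGeometry = JunctionGeometry()) -> float:
    """Interduplex angle (degrees) opposite the dye-dye distance ``c_A`` (Å).

    Law of cosines with equal straight arms ``a = b`` from ``geom``:
    θ = arccos((a² + b² − c²) / (2ab)).
    """
    a = b = geom.arm_length_A
    if c_A <= 0:
        raise GeometryError("dye separation c must be positive")
    if not (abs(a - b) < c_A < a + b):
        raise GeometryError(
            f"inconsistent geometry: c = {c_A} Å violates triangle inequality "
            f"for arms a = b = {a} Å"
        )
    cos_theta = (a**2 + b**2 - c_A**2) / (2 * a * b)
    return float(np.degrees(np.arccos(cos_theta)))
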