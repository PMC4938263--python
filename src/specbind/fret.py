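"""Förster resonance energy transfer: overlap integral, R0, E and distance.

The spectral overlap integral

    J = ∫ F(λ) ε(λ) λ⁴ dλ / ∫ F(λ) dλ

is evaluated by composite trapezoid quadrature on the union of the two
wavelength grids, with λ in nm and ε in M^-1 cm^-1, which gives J in
nm⁴ M^-1 cm^-1.  The same value is also expressed in cm³ M^-1 (factor
1e-28), the unit expected by the Förster-radius prefactor

    R0⁶ (cm⁶) = 8.79×10⁻²⁵ κ² n⁻⁴ φ J(cm³ M⁻¹)

with κ² the orientation factor, n the refractive index of the medium and
φ the donor quantum yield.  Transfer efficiency follows
``E = 1 − F/F0 = R0⁶/(R0⁶ + r⁶)``, and a donor–acceptor distance estimate
is only considered reliable inside the Förster window 0.5 R0 < r < 1.5 R0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, WindowError
from .spectra import Spectrum

__all__ = [
    "FretConfig",
    "FretResult",
    "OverlapIntegral",
    "J_NM4_TO_CM3",
    "overlap_integral",
    "forster_radius",
    "efficiency_from_intensity",
    "efficiency_from_distance",
    "distance_from_efficiency",
    "forster_window_check",
    "fret_analysis",
]

#: conversion of J from nm^4 M^-1 cm^-1 to cm^3 M^-1: (1 nm = 1e-7 cm)^4 / cm
J_NM4_TO_CM3 = 1e-28
#: prefactor of the R0^6 relation, cm^6 per (cm^3 M^-1) of J
R0_PREFACTOR = 8.79e-25
DEFAULT_RANGE_NM = (300.0, 400.0)


@dataclass(frozen=True)
class FretConfig:
    """Photophysical constants of the donor–acceptor pair.

    Defaults are the standard tryptophan-donor values: isotropic
    orientation factor κ² = 2/3, aqueous-buffer refractive index 1.336,
    donor quantum yield 0.15.
    """

    kappa_squared: float = 2.0 / 3.0
    refractive_index: float = 1.336
    quantum_yield: float = 0.15

    def __post_init__(self) -> None:
        if not 0 < self.kappa_squared <= 4:
            raise DomainError("kappa^2 must be in (0, 4]")
        if self.refractive_index <= 1:
            raise DomainError("refractive index must exceed 1")
        if not 0 < self.quantum_yield <= 1:
            raise DomainError("quantum yield must be in (0, 1]")


@dataclass(frozen=True)
class OverlapIntegral:
    """Spectral overlap integral in both unit dialects."""

    j_nm4_M_inv_cm_inv: float
    n_grid_points: int

    @property
    def j_cm3_M_inv(self) -> float:
        return self.j_nm4_M_inv_cm_inv * J_NM4_TO_CM3


@dataclass(frozen=True)
class FretResult:
    """Full FRET characterisation of one donor–acceptor pair."""

    j_nm4_M_inv_cm_inv: float
    j_cm3_M_inv: float
    r0_nm: float
    efficiency: float
    r_nm: float
    forster_window_ok: bool


def overlap_integral(donor_emission: Spectrum, acceptor_epsilon: Spectrum,
                     range_nm: tuple[float, float] = DEFAULT_RANGE_NM,
                     ) -> OverlapIntegral:
    """Trapezoid J = ∫F ε λ⁴ dλ / ∫F dλ over ``range_nm``.

    Both curves are linearly interpolated onto the union of their grids
    restricted to the intersection of ``range_nm`` with both spectra;
    nothing is ever extrapolated.  Invariant to rescaling the donor.
    """
    if acceptor_epsilon.kind != "molar_absorptivity":
        raise DomainError(
            "acceptor spectrum must be molar absorptivity (M^-1 cm^-1); "
            "convert absorbance with absorbance_to_molar_absorptivity"
        )
    lo = max(range_nm[0], donor_emission.range_nm[0],
             acceptor_epsilon.range_nm[0])
    hi = min(range_nm[1], donor_emission.range_nm[1],
             acceptor_epsilon.range_nm[1])
    if hi <= lo:
        raise WindowError(
            f"no grid overlap inside range {range_nm[0]}–{range_nm[1]} nm"
        )
    grid = np.union1d(donor_emission.wavelengths_nm,
                      acceptor_epsilon.wavelengths_nm)
    grid = grid[(grid >= lo) & (grid <= hi)]
    for edge in (lo, hi):
        if not np.isclose(grid, edge).any():
            grid = np.append(grid, edge)
    grid = np.sort(grid)
    f = donor_emission.interp(grid)
    eps = acceptor_epsilon.interp(grid)
    denom = float(np.trapezoid(f, grid))
    if denom <= 0:
        raise DomainError("donor emission integrates to zero over the range")
    num = float(np.trapezoid(f * eps * grid**4, grid))
    return OverlapIntegral(j_nm4_M_inv_cm_inv=num / denom,
                           n_grid_points=int(grid.size))


def forster_radius(j_nm4_M_inv_cm_inv: float,
                   config: FretConfig = FretConfig()) -> float:
    """Förster radius R0 in nm from J in nm⁴ M^-1 cm^-1.

    J is converted to cm³ M^-1 (×1e-28) before the
    ``R0⁶ = 8.79e-25 κ² n⁻⁴ φ J`` relation, whose result is in cm and
    returned in nm.
    """
    if j_nm4_M_inv_cm_inv < 0:
        raise DomainError("overlap integral must be >= 0")
    j_cm3 = j_nm4_M_inv_cm_inv * J_NM4_TO_CM3
    r0_cm6 = (R0_PREFACTOR * config.kappa_squared
              * config.refractive_index**-4 * config.quantum_yield * j_cm3)
    return float(r0_cm6 ** (1.0 / 6.0) * 1e7)


def efficiency_from_intensity(f: float, f0: float) -> float:
    """E = 1 − F/F0 from the donor intensity with and without acceptor."""
    if f0 <= 0 or f <= 0 or f > f0:
        raise DomainError("need 0 < F <= F0")
    return 1.0 - f / f0


def efficiency_from_distance(r_nm: float, r0_nm: float) -> float:
    """E = R0⁶ / (R0⁶ + r⁶)."""
    if r0_nm <= 0:
        raise DomainError("R0 must be positive")
    if r_nm < 0:
        raise DomainError("distance must be >= 0")
    ratio6 = (r_nm / r0_nm) ** 6
    return 1.0 / (1.0 + ratio6)


def distance_from_efficiency(efficiency: float, r0_nm: float) -> float:
    """r = R0 ((1−E)/E)^(1/6); defined only for 0 < E < 1."""
    if r0_nm <= 0:
        raise DomainError("R0 must be positive")
    if not 0 < efficiency < 1:
        raise DomainError("efficiency must lie strictly between 0 and 1")
    return r0_nm * ((1.0 - efficiency) / efficiency) ** (1.0 / 6.0)


def forster_window_check(r_nm: float, r0_nm: float) -> bool:
    """True iff 0.5 R0 < r < 1.5 R0 (strict), the reliable FRET range."""
    if r_nm <= 0 or r0_nm <= 0:
        raise DomainError("distances must be positive")
    return 0.5 * r0_nm < r_nm < 1.5 * r0_nm


def fret_analysis(donor_emission: Spectrum, acceptor_epsilon: Spectrum,
                  f: float, f0: float,
                  config: FretConfig = FretConfig(),
                  range_nm: tuple[float, float] = DEFAULT_RANGE_NM,
                  ) -> FretResult:
    """Full chain: J → R0 → E (from intensities) → r → window check.

    ``f``/``f0`` are the donor intensities with and without the acceptor at
    equimolar donor:acceptor concentration.
    """
    j = overlap_integral(donor_emission, acceptor_epsilon, range_nm)
    r0 = forster_radius(j.j_nm4_M_inv_cm_inv, config)
    e = efficiency_from_intensity(f, f0)
    r = distance_from_efficiency(e, r0)
    return FretResult(
        j_nm4_M_inv_cm_inv=j.j_nm4_M_inv_cm_inv, j_cm3_M_inv=j.j_cm3_M_inv,
        r0_nm=r0, efficiency=e, r_nm=r,
        forster_window_ok=forster_window_check(r, r0),
    )
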