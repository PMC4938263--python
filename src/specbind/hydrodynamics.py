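"""Stokes–Einstein sizing and condition-to-condition size-change reports.

The hydrodynamic radius of the equivalent Stokes sphere follows from the
translational diffusion coefficient via ``Rh = kB T / (6 π η D)``.  All
internal arithmetic is SI (m, s, Pa·s, K); nm appears only at the
reporting boundary.  A built-in handbook table supplies the viscosity of
water between 10 and 40 °C when the user does not provide one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError, InsufficientDataError

__all__ = [
    "BOLTZMANN_J_K",
    "HydroMeasurement",
    "SizeChangeReport",
    "stokes_einstein_radius",
    "diffusion_from_radius",
    "water_viscosity_Pa_s",
    "size_change_report",
]

BOLTZMANN_J_K = 1.380649e-23

# Viscosity of water, mPa·s, at integer Celsius temperatures (handbook
# values); linearly interpolated between entries.
_WATER_VISCOSITY_mPa_s = {
    10: 1.3059, 11: 1.2692, 12: 1.2338, 13: 1.2005, 14: 1.1683,
    15: 1.1382, 16: 1.1080, 17: 1.0790, 18: 1.0518, 19: 1.0259,
    20: 1.0016, 21: 0.9775, 22: 0.9544, 23: 0.9321, 24: 0.9107,
    25: 0.8900, 26: 0.8703, 27: 0.8512, 28: 0.8328, 29: 0.8145,
    30: 0.7978, 31: 0.7809, 32: 0.7647, 33: 0.7491, 34: 0.7340,
    35: 0.7194, 36: 0.7052, 37: 0.6915, 38: 0.6783, 39: 0.6654,
    40: 0.6529,
}
_VISC_T_C = np.array(sorted(_WATER_VISCOSITY_mPa_s))
_VISC_MPA_S = np.array([_WATER_VISCOSITY_mPa_s[t] for t in _VISC_T_C])


def water_viscosity_Pa_s(temperature_K: float) -> float:
    """Viscosity of water in Pa·s, 283–313 K, by table interpolation."""
    t_c = temperature_K - 273.15
    if not _VISC_T_C[0] <= t_c <= _VISC_T_C[-1]:
        raise DomainError(
            f"water viscosity table covers {_VISC_T_C[0]}–{_VISC_T_C[-1]} °C; "
            f"got {t_c:.2f} °C"
        )
    return float(np.interp(t_c, _VISC_T_C, _VISC_MPA_S)) * 1e-3


def stokes_einstein_radius(diffusion_m2_s: float, temperature_K: float,
                           viscosity_Pa_s: float) -> float:
    """Rh = kB T / (6 π η D), returned in nm."""
    if diffusion_m2_s <= 0 or temperature_K <= 0 or viscosity_Pa_s <= 0:
        raise DomainError("D, T and eta must all be positive")
    rh_m = BOLTZMANN_J_K * temperature_K / (
        6.0 * math.pi * viscosity_Pa_s * diffusion_m2_s)
    return rh_m * 1e9


def diffusion_from_radius(rh_nm: float, temperature_K: float,
                          viscosity_Pa_s: float) -> float:
    """Inverse Stokes–Einstein: D = kB T / (6 π η Rh), in m² s^-1."""
    if rh_nm <= 0 or temperature_K <= 0 or viscosity_Pa_s <= 0:
        raise DomainError("Rh, T and eta must all be positive")
    return BOLTZMANN_J_K * temperature_K / (
        6.0 * math.pi * viscosity_Pa_s * rh_nm * 1e-9)


@dataclass(frozen=True)
class HydroMeasurement:
    """One sizing measurement (one protein:ligand ratio condition).

    Either ``rh_nm`` is given directly (instrument output) or it is
    computed from ``diffusion_m2_s`` with ``temperature_K`` and
    ``viscosity_Pa_s`` (the latter looked up from the water table when
    omitted).  ``baseline`` marks the ligand-free condition.
    """

    label: str
    protein: str
    rh_nm: float | None = None
    diffusion_m2_s: float | None = None
    temperature_K: float | None = None
    viscosity_Pa_s: float | None = None
    polydispersity_pct: float | None = None
    baseline: bool = False

    def resolved_rh_nm(self) -> float:
        if self.rh_nm is not None:
            if self.rh_nm <= 0:
                raise DomainError(f"{self.label}: Rh must be positive")
            return self.rh_nm
        if self.diffusion_m2_s is None or self.temperature_K is None:
            raise ConfigurationError(
                f"{self.label}: need rh_nm, or diffusion_m2_s + temperature_K"
            )
        eta = (self.viscosity_Pa_s if self.viscosity_Pa_s is not None
               else water_viscosity_Pa_s(self.temperature_K))
        return stokes_einstein_radius(self.diffusion_m2_s,
                                      self.temperature_K, eta)


@dataclass(frozen=True)
class SizeChangeReport:
    """Per-protein Rh trajectory relative to the ligand-free baseline."""

    protein: str
    baseline_label: str
    baseline_rh_nm: float
    conditions: tuple  # of dicts: label, rh_nm, change_pct, call
    overall_call: str


def _direction_call(change_pct: float, threshold_pct: float) -> str:
    if change_pct < -threshold_pct:
        return "compaction"
    if change_pct > threshold_pct:
        return "expansion/aggregation"
    return "no change"


def size_change_report(measurements, threshold_pct: float = 5.0,
                       ) -> list[SizeChangeReport]:
    """Percent Rh change of each condition vs its protein's baseline.

    Changes smaller than ``threshold_pct`` (default 5%, below typical
    instrument polydispersity) are called "no change".  Each protein group
    needs >= 2 measurements and exactly one marked ``baseline``.
    """
    groups: dict[str, list[HydroMeasurement]] = {}
    for m in measurements:
        groups.setdefault(m.protein, []).append(m)
    reports = []
    for protein, group in groups.items():
        if len(group) < 2:
            raise InsufficientDataError(
                f"{protein}: need >= 2 measurements to report size changes"
            )
        baselines = [m for m in group if m.baseline]
        if len(baselines) != 1:
            raise ConfigurationError(
                f"{protein}: exactly one ligand-free baseline required, "
                f"found {len(baselines)}"
            )
        base = baselines[0]
        rh0 = base.resolved_rh_nm()
        conditions = []
        calls = set()
        for m in group:
            rh = m.resolved_rh_nm()
            change = (rh - rh0) / rh0 * 100.0
            call = _direction_call(change, threshold_pct) if m is not base else "baseline"
            if m is not base:
                calls.add(call)
            conditions.append({
                "label": m.label, "rh_nm": rh, "change_pct": change,
                "polydispersity_pct": m.polydispersity_pct, "call": call,
            })
        overall = calls.pop() if len(calls) == 1 else "mixed"
        reports.append(SizeChangeReport(
            protein=protein, baseline_label=base.label, baseline_rh_nm=rh0,
            conditions=tuple(conditions), overall_call=overall,
        ))
    return reports
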