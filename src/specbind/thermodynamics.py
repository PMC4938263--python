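"""Binding thermodynamics from multi-temperature binding constants.

Gibbs free energy per temperature from ``ΔG° = −RT ln Kb``; enthalpy and
entropy from the van't Hoff line ``ln Kb = −ΔH/(RT) + ΔS/R`` fitted by
unweighted OLS (with only three temperatures any weighting is
unidentifiable); and a Ross–Subramanian classification of the dominant
interaction forces from the signs of ΔH and ΔS.

Units follow spectroscopic convention: R = 1.987 cal mol^-1 K^-1, ΔG and
ΔH in kcal/mol, ΔS in cal mol^-1 K^-1.  Because published tables sometimes
label TΔS (kcal/mol) as "ΔS", results carry both ΔS and per-temperature
TΔS = ΔH − ΔG explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InsufficientDataError

__all__ = [
    "R_CAL_MOL_K",
    "ThermoResult",
    "delta_g",
    "vant_hoff_fit",
    "classify_forces",
    "kb_from_thermo",
]

#: gas constant in cal mol^-1 K^-1
R_CAL_MOL_K = 1.987


@dataclass(frozen=True)
class ThermoResult:
    """Thermodynamic parameters of binding from a (T, Kb) series."""

    temperatures_K: tuple[float, ...]
    kb_M_inv: tuple[float, ...]
    delta_g_kcal_mol: tuple[float, ...]
    t_delta_s_kcal_mol: tuple[float, ...]  # ΔH − ΔG at each T
    delta_h_kcal_mol: float
    delta_s_cal_mol_K: float
    vant_hoff_slope_K: float  # = −ΔH/R
    vant_hoff_intercept: float  # = ΔS/R
    r_squared: float
    r_gas_cal_mol_K: float
    force_call: str


def delta_g(kb_M_inv: float, temperature_K: float,
            r: float = R_CAL_MOL_K) -> float:
    """Standard free energy of binding, −RT ln Kb, in kcal/mol."""
    if kb_M_inv <= 0 or temperature_K <= 0:
        raise DomainError("Kb and T must be positive")
    return -r * temperature_K * math.log(kb_M_inv) / 1000.0


def classify_forces(delta_h_kcal_mol: float, delta_s_cal_mol_K: float,
                    h_zero_threshold_kcal: float = 1.0) -> str:
    """Ross–Subramanian sign rules for the dominant binding forces.

    ΔH≈0 with ΔS>0 → electrostatic/ionic; ΔH<0 and ΔS<0 → hydrogen
    bonding / van der Waals; ΔH>0 and ΔS>0 → hydrophobic; anything else is
    mixed/indeterminate.  The "ΔH≈0" band defaults to 1 kcal/mol.
    """
    dh, ds = delta_h_kcal_mol, delta_s_cal_mol_K
    if abs(dh) <= h_zero_threshold_kcal and ds > 0:
        return "electrostatic/ionic"
    if dh < 0 and ds < 0:
        return "hydrogen bonding / van der Waals"
    if dh > 0 and ds > 0:
        return "hydrophobic"
    return "mixed/indeterminate"


def vant_hoff_fit(points, r: float = R_CAL_MOL_K,
                  h_zero_threshold_kcal: float = 1.0) -> ThermoResult:
    """OLS of ln Kb against 1/T; ΔH from the slope, ΔS from the intercept.

    Assumes ΔH and ΔS temperature-independent over the fitted range.
    Also populates per-temperature ΔG = −RT ln Kb and TΔS = ΔH − ΔG.

    Parameters
    ----------
    points:
        Iterable of ``(temperature_K, kb_M_inv)`` pairs, Kb > 0.
    """
    pts = [(float(t), float(kb)) for t, kb in points]
    temps = [t for t, _ in pts]
    if len(set(temps)) < 2:
        raise InsufficientDataError("need >= 2 distinct temperatures")
    if any(t <= 0 for t, _ in pts) or any(kb <= 0 for _, kb in pts):
        raise DomainError("temperatures and Kb must be positive")
    pts.sort()
    t_arr = np.array([t for t, _ in pts])
    kb_arr = np.array([kb for _, kb in pts])
    x = 1.0 / t_arr
    y = np.log(kb_arr)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    dh_kcal = -r * float(slope) / 1000.0
    ds_cal = r * float(intercept)
    dg = tuple(delta_g(kb, t, r) for t, kb in pts)
    tds = tuple(dh_kcal - g for g in dg)
    return ThermoResult(
        temperatures_K=tuple(t_arr), kb_M_inv=tuple(kb_arr),
        delta_g_kcal_mol=dg, t_delta_s_kcal_mol=tds,
        delta_h_kcal_mol=dh_kcal, delta_s_cal_mol_K=ds_cal,
        vant_hoff_slope_K=float(slope), vant_hoff_intercept=float(intercept),
        r_squared=min(max(r2, 0.0), 1.0), r_gas_cal_mol_K=r,
        force_call=classify_forces(dh_kcal, ds_cal, h_zero_threshold_kcal),
    )


def kb_from_thermo(delta_h_kcal_mol: float, delta_s_cal_mol_K: float,
                   temperature_K: float, r: float = R_CAL_MOL_K) -> float:
    """Invert the van't Hoff line: Kb = exp(−ΔH/(RT) + ΔS/R)."""
    if temperature_K <= 0:
        raise DomainError("temperature must be positive")
    return math.exp(-delta_h_kcal_mol * 1000.0 / (r * temperature_K)
                    + delta_s_cal_mol_K / r)
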