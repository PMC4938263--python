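"""Fluorescence-quenching titration analysis.

Implements the two linear-transform estimators routinely applied to
protein–ligand quenching titrations:

* the Stern–Volmer fit ``F0/F = 1 + Ksv [Q]`` whose slope Ksv (M^-1)
  measures quenching efficiency and whose ratio to the fluorophore
  lifetime tau0 gives the bimolecular quenching rate constant
  ``kq = Ksv / tau0``;
* the double-logarithmic ("modified Stern–Volmer") fit
  ``log10(F0/F − 1) = log10 Kb + n log10 [Q]`` giving the binding constant
  Kb (M^-1) and the number of binding sites n.

On top of the fits sit two classifiers: the static-vs-dynamic quenching
mechanism call (temperature trend of Ksv combined with kq against the
diffusion-controlled limit 2×10^10 M^-1 s^-1) and the site-marker
displacement analysis that identifies the primary drug-binding site of
serum albumin (Sudlow site I probed by warfarin/phenylbutazone, site II by
diazepam) from the drop in Ksv when a marker pre-occupies a site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (ConfigurationError, DomainError, FormatError,
                     InsufficientDataError)

__all__ = [
    "TitrationSeries",
    "QuenchingFit",
    "BindingFit",
    "MechanismCall",
    "DisplacementReport",
    "DIFFUSION_LIMIT_M_INV_S_INV",
    "DEFAULT_TAU0_S",
    "read_titration",
    "write_titration",
    "stern_volmer_fit",
    "modified_sv_fit",
    "classify_mechanism",
    "displacement_analysis",
]

#: maximum diffusion-controlled (scatter collision) quenching rate constant
DIFFUSION_LIMIT_M_INV_S_INV = 2.0e10
#: average integral fluorescence lifetime of tryptophan, seconds
DEFAULT_TAU0_S = 1e-9


@dataclass(frozen=True)
class TitrationSeries:
    """Fluorescence vs quencher concentration at fixed protein and temperature.

    ``q_M`` is the total added quencher concentration (no free-ligand
    correction).  ``f0`` is the fluorescence at [Q]=0; if the [Q]=0 point is
    present in the series its F must equal ``f0``.
    """

    q_M: np.ndarray
    f_au: np.ndarray
    f0: float
    protein_label: str = ""
    protein_conc_M: float | None = None
    temperature_K: float | None = None
    marker_label: str | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.q_M, dtype=float)
        f = np.asarray(self.f_au, dtype=float)
        object.__setattr__(self, "q_M", q)
        object.__setattr__(self, "f_au", f)
        if q.shape != f.shape or q.ndim != 1:
            raise FormatError("q_M and f_au must be 1-D arrays of equal length")
        if np.any(q < 0):
            raise DomainError("quencher concentrations must be >= 0")
        if np.any(np.diff(q) <= 0):
            raise DomainError("quencher concentrations must be strictly increasing")
        if self.f0 <= 0 or np.any(f <= 0):
            raise DomainError("fluorescence intensities must be positive")
        zero = np.isclose(q, 0.0)
        if zero.any() and not np.isclose(f[zero][0], self.f0):
            raise DomainError("F at [Q]=0 must equal f0")

    def __len__(self) -> int:
        return int(self.q_M.size)


@dataclass(frozen=True)
class QuenchingFit:
    """Stern–Volmer fit result: Ksv, intercept, kq = Ksv/tau0."""

    ksv_M_inv: float
    intercept: float
    kq_M_inv_s_inv: float
    tau0_s: float
    r_squared: float
    n_points_used: int
    intercept_flagged: bool = False  # |intercept − 1| > 0.1


@dataclass(frozen=True)
class BindingFit:
    """Double-log fit result: binding constant Kb and site number n."""

    kb_M_inv: float
    n_sites: float
    log10_kb: float
    r_squared: float
    n_points_used: int
    excluded_points: tuple[int, ...] = ()


@dataclass(frozen=True)
class MechanismCall:
    """Static vs dynamic quenching classification.

    A static call requires Ksv strictly decreasing with temperature AND all
    kq above the diffusion limit; a dynamic call requires the converse on
    both axes; anything else is ambiguous.
    """

    call: str  # static | dynamic | ambiguous
    ksv_temperature_trend: str  # decreasing | increasing | flat
    kq_exceeds_diffusion_limit: bool
    diffusion_limit_M_inv_s_inv: float = DIFFUSION_LIMIT_M_INV_S_INV


@dataclass(frozen=True)
class DisplacementReport:
    """Per-marker Ksv drop and the resulting primary-site call."""

    ksv_free_M_inv: float
    markers: dict = field(default_factory=dict)
    # markers: label -> {"ksv_M_inv", "fractional_decrease", "site"}
    primary_site_call: str = "none"
    primary_marker: str | None = None
    secondary_sites: tuple[str, ...] = ()


def read_titration(path: str | Path, f0: float | None = None,
                   **meta) -> TitrationSeries:
    """Read a delimited titration table (quencher_conc_M, fluorescence).

    Comma, tab or whitespace delimited, optional header.  If a [Q]=0 row is
    present its F is used as f0; otherwise ``f0`` must be given.  Extra
    keyword arguments become series metadata (protein_label, temperature_K,
    protein_conc_M, marker_label).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"{path.name}: cannot parse titration table: {exc}")
    if df.shape[1] < 2:
        raise FormatError(f"{path.name}: expected two columns")
    # tolerate headerless files (pandas will have taken row 1 as header)
    try:
        q = df.iloc[:, 0].astype(float).to_numpy()
        f = df.iloc[:, 1].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path.name}: non-numeric titration values: {exc}")
    if f0 is None:
        zero = np.isclose(q, 0.0)
        if not zero.any():
            raise FormatError(
                f"{path.name}: no [Q]=0 row and no explicit f0 supplied"
            )
        f0 = float(f[zero][0])
    order = np.argsort(q)
    return TitrationSeries(q[order], f[order], float(f0), **meta)


def write_titration(series: TitrationSeries, path: str | Path,
                    precision: int = 8) -> None:
    path = Path(path)
    lines = ["quencher_conc_M,fluorescence"]
    for q, f in zip(series.q_M, series.f_au):
        lines.append(f"{q:.{precision}e},{f:.{precision}f}")
    path.write_text("\n".join(lines) + "\n")


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and r^2 of an ordinary least-squares line."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-30 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), float(min(max(r2, 0.0), 1.0))


def stern_volmer_fit(series: TitrationSeries,
                     tau0_s: float = DEFAULT_TAU0_S) -> QuenchingFit:
    """OLS of F0/F against [Q] with a free intercept.

    The intercept is not forced to 1 (a departure would hide blank
    subtraction problems); it is flagged when |intercept − 1| > 0.1.
    ``kq = Ksv / tau0``.
    """
    if tau0_s <= 0:
        raise DomainError("tau0 must be positive")
    mask = series.q_M > 0
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"Stern–Volmer fit needs >= 3 points with [Q] > 0, "
            f"got {int(mask.sum())}"
        )
    x = series.q_M[mask]
    y = series.f0 / series.f_au[mask]
    slope, intercept, r2 = _ols(x, y)
    return QuenchingFit(
        ksv_M_inv=slope, intercept=intercept,
        kq_M_inv_s_inv=slope / tau0_s, tau0_s=tau0_s,
        r_squared=r2, n_points_used=int(mask.sum()),
        intercept_flagged=abs(intercept - 1.0) > 0.1,
    )


def modified_sv_fit(series: TitrationSeries) -> BindingFit:
    """OLS of log10(F0/F − 1) against log10 [Q].

    Slope = number of binding sites n; intercept = log10 Kb.  Points with
    F0/F − 1 <= 0 (logarithm undefined, e.g. no measurable quenching yet)
    are excluded deterministically and their indices recorded.
    """
    ratio = series.f0 / series.f_au - 1.0
    positive_q = series.q_M > 0
    usable = positive_q & (ratio > 0)
    excluded = tuple(int(i) for i in np.nonzero(positive_q & ~usable)[0])
    if usable.sum() < 3:
        raise InsufficientDataError(
            f"modified Stern–Volmer fit needs >= 3 usable points, "
            f"got {int(usable.sum())}"
        )
    x = np.log10(series.q_M[usable])
    y = np.log10(ratio[usable])
    slope, intercept, r2 = _ols(x, y)
    if slope <= 0:
        raise DomainError(
            f"fitted number of binding sites n = {slope:g} is non-positive; "
            "the series does not follow a binding isotherm"
        )
    return BindingFit(
        kb_M_inv=float(10.0**intercept), n_sites=slope,
        log10_kb=intercept, r_squared=r2,
        n_points_used=int(usable.sum()), excluded_points=excluded,
    )


def classify_mechanism(fits: Sequence[QuenchingFit],
                       temperatures_K: Sequence[float]) -> MechanismCall:
    """Static/dynamic call from the temperature trend of Ksv and kq.

    Static quenching (ground-state complex) destabilises with temperature,
    so Ksv falls as T rises, and its apparent kq exceeds the
    diffusion-controlled collision limit; dynamic (collisional) quenching
    shows the converse.  Mixed evidence yields ``ambiguous``.
    """
    if len(fits) != len(temperatures_K):
        raise DomainError("fits and temperatures must align")
    if len(fits) < 2:
        raise InsufficientDataError("need fits at >= 2 temperatures")
    temps = [float(t) for t in temperatures_K]
    if len(set(temps)) != len(temps):
        raise DomainError("duplicate temperatures")
    order = np.argsort(temps)
    ksv = [fits[i].ksv_M_inv for i in order]
    diffs = np.diff(ksv)
    if np.all(diffs < 0):
        trend = "decreasing"
    elif np.all(diffs > 0):
        trend = "increasing"
    else:
        trend = "flat"
    exceeds = all(f.kq_M_inv_s_inv > DIFFUSION_LIMIT_M_INV_S_INV for f in fits)
    if trend == "decreasing" and exceeds:
        call = "static"
    elif trend == "increasing" and not exceeds:
        call = "dynamic"
    else:
        call = "ambiguous"
    return MechanismCall(call=call, ksv_temperature_trend=trend,
                         kq_exceeds_diffusion_limit=exceeds)


def displacement_analysis(free: QuenchingFit,
                          with_markers: Mapping[str, QuenchingFit],
                          site_map: Mapping[str, str],
                          secondary_threshold: float = 0.5,
                          ) -> DisplacementReport:
    """Primary binding site from the Ksv drop caused by each site marker.

    ``fractional_decrease = 1 − Ksv_with_marker / Ksv_free``; the marker
    with the largest decrease defines the primary site.  Any other site
    whose marker decrease exceeds ``secondary_threshold`` is flagged as a
    secondary site.  All decreases <= 0 means no competition ("none").
    """
    if not with_markers:
        raise InsufficientDataError("need at least one marker fit")
    markers: dict[str, dict] = {}
    for label, fit in with_markers.items():
        if label not in site_map:
            raise ConfigurationError(f"marker {label!r} missing from site_map")
        markers[label] = {
            "ksv_M_inv": fit.ksv_M_inv,
            "fractional_decrease": 1.0 - fit.ksv_M_inv / free.ksv_M_inv,
            "site": site_map[label],
        }
    best = max(markers, key=lambda m: markers[m]["fractional_decrease"])
    if markers[best]["fractional_decrease"] <= 0:
        return DisplacementReport(ksv_free_M_inv=free.ksv_M_inv,
                                  markers=markers, primary_site_call="none")
    primary_site = markers[best]["site"]
    secondary = tuple(sorted({
        m["site"] for m in markers.values()
        if m["site"] != primary_site
        and m["fractional_decrease"] > secondary_threshold
    }))
    return DisplacementReport(
        ksv_free_M_inv=free.ksv_M_inv, markers=markers,
        primary_site_call=primary_site, primary_marker=best,
        secondary_sites=secondary,
    )
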