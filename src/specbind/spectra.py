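"""Spectrum container, file I/O and peak/shift arithmetic.

A :class:`Spectrum` is a sampled optical curve — emission intensity,
absorbance, molar absorptivity or a synchronous scan — on a strictly
increasing wavelength grid in nanometres.  The operations here are the
plumbing every downstream stage relies on: blank subtraction, the
Beer–Lambert conversion of absorbance to molar absorptivity, peak location
with sub-grid parabolic refinement (so a 3 nm shift is resolvable on a
1 nm grid), signed peak shifts (negative = blue shift) and hyperchromicity
ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import DomainError, FormatError, GridError, WindowError

__all__ = [
    "Spectrum",
    "PeakReport",
    "SPECTRUM_KINDS",
    "read_spectrum",
    "write_spectrum",
    "subtract_blank",
    "absorbance_to_molar_absorptivity",
    "peak_report",
    "hyperchromicity",
]

SPECTRUM_KINDS = ("emission", "absorbance", "molar_absorptivity", "synchronous")

#: wavelengths closer than this (nm) are considered the same grid point
GRID_TOL_NM = 1e-6


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths_nm:
        Strictly increasing wavelength grid in nm, length >= 2.
    signal:
        Signal values, same length as the grid.  Fluorescence in arbitrary
        units, absorbance in AU, or molar absorptivity in M^-1 cm^-1.
        Absorbance-like kinds must be non-negative.
    kind:
        One of ``emission``, ``absorbance``, ``molar_absorptivity``,
        ``synchronous``.
    meta:
        Free-form metadata: ``temperature_K``, ``excitation_nm``,
        ``delta_lambda_nm`` (synchronous scans), ``label``.
    """

    wavelengths_nm: np.ndarray
    signal: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        sig = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "signal", sig)
        if self.kind not in SPECTRUM_KINDS:
            raise DomainError(f"unknown spectrum kind {self.kind!r}")
        if wl.ndim != 1 or wl.size < 2:
            raise FormatError("a spectrum needs at least 2 wavelength points")
        if sig.shape != wl.shape:
            raise FormatError(
                f"signal length {sig.size} != wavelength length {wl.size}"
            )
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(sig)):
            raise FormatError("non-finite values in spectrum")
        if np.any(np.diff(wl) <= 0):
            raise FormatError("wavelength grid must be strictly increasing")
        if self.kind in ("absorbance", "molar_absorptivity") and np.any(sig < 0):
            raise DomainError(f"{self.kind} spectrum has negative values")

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    @property
    def range_nm(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def interp(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Linear interpolation of the signal; never extrapolates."""
        wl = np.asarray(wavelengths_nm, dtype=float)
        lo, hi = self.range_nm
        if np.any(wl < lo - GRID_TOL_NM) or np.any(wl > hi + GRID_TOL_NM):
            raise WindowError(
                f"requested wavelengths outside spectrum range [{lo}, {hi}] nm"
            )
        return np.interp(wl, self.wavelengths_nm, self.signal)

    def with_signal(self, signal: np.ndarray, kind: str | None = None) -> "Spectrum":
        return replace(self, signal=np.asarray(signal, dtype=float),
                       kind=self.kind if kind is None else kind)


@dataclass(frozen=True)
class PeakReport:
    """Peak position/intensity of a sample spectrum relative to a reference.

    ``shift_nm`` is signed: lambda_max(sample) - lambda_max(reference), so a
    negative shift is a move toward shorter wavelength (blue shift) and a
    positive one a red shift.
    """

    lambda_max_nm: float
    intensity_at_max: float
    reference_lambda_max_nm: float
    reference_intensity_at_max: float
    shift_nm: float
    intensity_ratio: float
    sign_convention: str = "negative shift_nm = blue shift"

    def to_dict(self) -> dict:
        return {
            "lambda_max_nm": self.lambda_max_nm,
            "shift_nm": self.shift_nm,
            "intensity_ratio": self.intensity_ratio,
            "reference_lambda_max_nm": self.reference_lambda_max_nm,
            "sign_convention": self.sign_convention,
        }


def _sniff_split(line: str) -> list[str]:
    if "," in line:
        return [f.strip() for f in line.split(",")]
    if "\t" in line:
        return [f.strip() for f in line.split("\t")]
    return line.split()


def read_spectrum(path: str | Path, kind: str,
                  meta: Mapping | None = None) -> Spectrum:
    """Read a two-column delimited text spectrum (wavelength nm, signal).

    Comma, tab or whitespace delimiters are auto-detected; one optional
    header line is tolerated.  Rows are sorted by wavelength; duplicate
    wavelengths are rejected with the offending line number.
    """
    path = Path(path)
    rows: list[tuple[float, float]] = []
    lines: list[tuple[int, float, float]] = []
    header_seen = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = _sniff_split(line.strip())
        try:
            wl, sig = float(fields[0]), float(fields[1])
        except (ValueError, IndexError):
            if not rows and not header_seen:
                header_seen = True  # one optional header line
                continue
            raise FormatError(
                f"{path.name} line {lineno}: expected two numeric columns, "
                f"got {line.strip()!r}"
            )
        rows.append((wl, sig))
        lines.append((lineno, wl, sig))
    if len(rows) < 2:
        raise FormatError(f"{path.name}: fewer than 2 data points")
    order = np.argsort([r[0] for r in rows], kind="stable")
    wl = np.array([rows[i][0] for i in order])
    sig = np.array([rows[i][1] for i in order])
    dup = np.nonzero(np.diff(wl) < GRID_TOL_NM)[0]
    if dup.size:
        bad_wl = wl[dup[0] + 1]
        matches = [ln for ln, w, _ in lines if abs(w - bad_wl) < GRID_TOL_NM]
        lineno = matches[1]  # the repeated occurrence, in file order
        raise FormatError(
            f"{path.name} line {lineno}: duplicate wavelength {bad_wl:g} nm"
        )
    return Spectrum(wl, sig, kind, dict(meta or {}))


def write_spectrum(spectrum: Spectrum, path: str | Path,
                   delimiter: str = ",", precision: int = 6,
                   header: bool = True) -> None:
    """Write a spectrum as two-column delimited text (inverse of read)."""
    path = Path(path)
    lines = []
    if header:
        lines.append(f"wavelength_nm{delimiter}signal")
    for wl, sig in zip(spectrum.wavelengths_nm, spectrum.signal):
        lines.append(f"{wl:.{precision}f}{delimiter}{sig:.{precision}f}")
    path.write_text("\n".join(lines) + "\n")


def _grids_match(a: Spectrum, b: Spectrum, tol_nm: float = GRID_TOL_NM) -> bool:
    return (len(a) == len(b)
            and bool(np.all(np.abs(a.wavelengths_nm - b.wavelengths_nm) <= tol_nm)))


def subtract_blank(sample: Spectrum, blank: Spectrum,
                   tol_nm: float = GRID_TOL_NM) -> Spectrum:
    """Pointwise sample − blank on identical grids; meta inherited from sample."""
    if not _grids_match(sample, blank, tol_nm):
        raise GridError("sample and blank wavelength grids differ")
    sig = sample.signal - blank.signal
    if sample.kind in ("absorbance", "molar_absorptivity"):
        # blank subtraction can produce tiny negatives from noise; clip at 0
        sig = np.clip(sig, 0.0, None)
    return Spectrum(sample.wavelengths_nm.copy(), sig, sample.kind,
                    dict(sample.meta))


def absorbance_to_molar_absorptivity(a: Spectrum, concentration_M: float,
                                     path_cm: float = 1.0) -> Spectrum:
    """Beer–Lambert: epsilon(lambda) = A(lambda) / (c * l), in M^-1 cm^-1."""
    if a.kind != "absorbance":
        raise DomainError(f"expected an absorbance spectrum, got kind={a.kind!r}")
    if concentration_M <= 0 or path_cm <= 0:
        raise DomainError("concentration and path length must be positive")
    return Spectrum(a.wavelengths_nm.copy(),
                    a.signal / (concentration_M * path_cm),
                    "molar_absorptivity", dict(a.meta))


def _locate_peak(spectrum: Spectrum, window_nm: tuple[float, float] | None,
                 refine: bool) -> tuple[float, float]:
    wl, sig = spectrum.wavelengths_nm, spectrum.signal
    if window_nm is not None:
        lo, hi = window_nm
        mask = (wl >= lo - GRID_TOL_NM) & (wl <= hi + GRID_TOL_NM)
        if not mask.any():
            raise WindowError(
                f"window [{lo}, {hi}] nm does not overlap the spectrum grid"
            )
        idx = np.nonzero(mask)[0]
        wl, sig = wl[idx], sig[idx]
    i = int(np.argmax(sig))
    lam, peak = float(wl[i]), float(sig[i])
    if refine and 0 < i < len(wl) - 1:
        x, y = wl[i - 1:i + 2], sig[i - 1:i + 2]
        coef = np.polyfit(x, y, 2)
        if coef[0] < 0:  # genuine maximum
            xv = -coef[1] / (2.0 * coef[0])
            if x[0] <= xv <= x[2]:
                lam = float(xv)
                peak = float(np.polyval(coef, xv))
    return lam, peak


def peak_report(sample: Spectrum, reference: Spectrum,
                window_nm: tuple[float, float] | None = None,
                refine: bool = True) -> PeakReport:
    """Locate peak maxima and report the signed shift of sample vs reference.

    The maximum is located by argmax over the window and refined by a
    three-point parabola through the maximum and its neighbours when the
    maximum is interior — without this a 1 nm grid quantizes small
    synchronous-scan shifts.  ``shift_nm = lambda_max(sample) −
    lambda_max(reference)``; negative means blue shift.
    """
    s_lam, s_int = _locate_peak(sample, window_nm, refine)
    r_lam, r_int = _locate_peak(reference, window_nm, refine)
    ratio = s_int / r_int if r_int > 0 else float("nan")
    return PeakReport(
        lambda_max_nm=s_lam, intensity_at_max=s_int,
        reference_lambda_max_nm=r_lam, reference_intensity_at_max=r_int,
        shift_nm=s_lam - r_lam, intensity_ratio=ratio,
    )


def hyperchromicity(sample: Spectrum, reference: Spectrum,
                    lambda_nm: float) -> float:
    """Signal ratio sample/reference at one wavelength (>1 = hyperchromic).

    Both spectra are linearly interpolated at ``lambda_nm``.
    """
    s = float(sample.interp([lambda_nm])[0])
    r = float(reference.interp([lambda_nm])[0])
    if r <= 0:
        raise DomainError(f"reference signal is {r:g} <= 0 at {lambda_nm} nm")
    return s / r
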