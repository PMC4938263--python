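from fractions import Fraction

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


def ols_oracle(x, y):
    """Closed-form least-squares line by exact rational normal equations.

    Independent of every fitting path in the package: the inputs are
    converted to Fractions and slope/intercept come from the 2x2 normal
    equations solved exactly.
    """
    xs = [Fraction(float(v)) for v in x]
    ys = [Fraction(float(v)) for v in y]
    n = len(xs)
    sx, sy = sum(xs), sum(ys)
    sxx = sum(v * v for v in xs)
    sxy = sum(a * b for a, b in zip(xs, ys))
    det = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / det
    intercept = (sxx * sy - sx * sxy) / det
    return float(slope), float(intercept)


@pytest.fixture
def spectrum_file(tmp_path):
    """Write a two-column spectrum text file and return its path."""

    def _write(rows, name="spec.csv", header="wavelength,signal",
               delimiter=","):
        lines = [header] if header else []
        lines += [delimiter.join(str(v) for v in row) for row in rows]
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def gaussian_spectrum():
    from specbind import Spectrum

    def _make(center, sigma, peak=1.0, kind="emission", lo=250.0, hi=500.0,
              step=1.0):
        wl = np.arange(lo, hi + step / 2, step)
        sig = peak * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
        return Spectrum(wl, sig, kind)

    return _make
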