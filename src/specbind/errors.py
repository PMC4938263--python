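"""Exception hierarchy shared by every specbind module."""


class SpecbindError(Exception):
    """Base class for all package errors."""


class FormatError(SpecbindError, ValueError):
    """A data file violates the expected two-column / tabular layout."""


class GridError(SpecbindError, ValueError):
    """Two spectra that must share a wavelength grid do not."""


class WindowError(SpecbindError, ValueError):
    """A requested wavelength window has no overlap with the data."""


class DomainError(SpecbindError, ValueError):
    """A numeric argument is outside its physical domain."""


class InsufficientDataError(SpecbindError, ValueError):
    """Too few usable points to perform a fit."""


class ConfigurationError(SpecbindError, ValueError):
    """A study configuration is incomplete or inconsistent."""
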