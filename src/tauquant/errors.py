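"""Exception hierarchy shared across the analysis stages.

``exit_code`` is what the command-line layer returns to the shell:
2 for input/validation problems, 3 for fits that cannot be performed.
"""


class TauquantError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(TauquantError, ValueError):
    """Malformed or physically impossible input data or configuration."""

    exit_code = 2


class FitError(TauquantError, RuntimeError):
    """A model fit could not be carried out on the given data."""

    exit_code = 3


class NoQuenchError(FitError):
    """Fluorescence does not decrease with quencher: no binding signal."""


class NonPhysicalFitError(FitError):
    """Fitted Stern-Volmer line has a non-positive slope or intercept."""


class NoDoseResponseError(FitError):
    """Effect does not increase with dose; an IC50 is undefined."""
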