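"""Exception hierarchy for the MCDA pipeline.

Every stage raises a subclass of :class:`EvidemError` so the CLI can tag
failures with the stage that produced them and exit nonzero.
"""


class EvidemError(Exception):
    """Base class for all package errors."""


class ValidationError(EvidemError, ValueError):
    """An input value violates its contract (range, type, scale)."""


class StructuralError(EvidemError):
    """Inputs are individually valid but do not fit together
    (missing criteria, mismatched frameworks, empty panels)."""


class NumericalError(EvidemError):
    """A numerical routine failed to converge or produced an invalid result."""
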