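"""Exception hierarchy.

``ValidationError`` covers malformed models/inputs (CLI exit code 2);
``NumericalError`` covers solver failures (CLI exit code 3).
"""


class EfmcostError(Exception):
    """Base class for all package errors."""


class ValidationError(EfmcostError, ValueError):
    """A model, document or argument violates an invariant."""


class InfeasibleStateError(EfmcostError):
    """An EFM cannot operate at the given metabolite state (saturation = 0)."""


class NumericalError(EfmcostError):
    """A solver failed to produce a usable result."""
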