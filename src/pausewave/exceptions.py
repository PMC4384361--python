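"""Exception hierarchy.

All input-validation failures raise :class:`ValidationError` (a ``ValueError``)
so callers — in particular the CLI — can distinguish bad input (exit code 2)
from genuine bugs.
"""


class ValidationError(ValueError):
    """Invalid input data or parameters."""


class PatternError(ValidationError):
    """A regular-expression pattern failed to compile."""


class DegenerateEnergyError(ValidationError):
    """Total detail energy is zero, so power fractions are undefined."""
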