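"""Exception hierarchy.

All package errors derive from :class:`PolCoherenceError` so callers can
catch them with a single ``except``; the subclasses distinguish malformed
files from semantically invalid data and from inputs on which a statistic
is undefined.
"""


class PolCoherenceError(Exception):
    """Base class for all errors raised by polcoherence."""


class ValidationError(PolCoherenceError, ValueError):
    """Data violates an invariant (negative TPM, duplicate id, bad class label...)."""


class FormatError(PolCoherenceError, ValueError):
    """A file is structurally malformed (missing column, dimension mismatch...)."""


class DegenerateInputError(PolCoherenceError, ValueError):
    """A statistic is undefined on this input (e.g. zero-variance gene)."""


class ParameterError(PolCoherenceError, ValueError):
    """An argument is outside its documented domain."""
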