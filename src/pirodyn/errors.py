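"""Exception hierarchy.

Argument errors signal a caller mistake (bad counts, mixed labels,
impossible settings); degenerate-input errors signal data on which the
requested quantity is undefined (constant series, zero-diameter clouds,
affinely dependent point sets).
"""


class PirodynError(Exception):
    """Base class for all package errors."""


class ArgumentError(PirodynError, ValueError):
    """An argument violates a precondition."""


class DegenerateInputError(PirodynError, ValueError):
    """The input data is degenerate for the requested computation."""
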