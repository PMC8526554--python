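"""Exception hierarchy shared across the pipeline.

``InputError`` maps to CLI exit code 2 (malformed or inconsistent inputs),
``ComputationError`` to exit code 3 (numeric failure inside a stage).
"""


class DynstatesError(Exception):
    """Base class for all package errors."""


class InputError(DynstatesError):
    """Malformed, missing, or inconsistent input artifacts."""


class ComputationError(DynstatesError):
    """A numeric procedure failed (non-convergence, degenerate data)."""
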