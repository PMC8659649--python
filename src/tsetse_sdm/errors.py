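"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class TsetseSdmError(Exception):
    """Base class for all package errors."""


class ConfigError(TsetseSdmError):
    """Invalid configuration or parameter value."""


class DataError(TsetseSdmError):
    """Malformed, inconsistent or insufficient input data."""


class NumericalError(TsetseSdmError):
    """Numerical failure (non-convergence, singular system)."""


class DegenerateNullError(NumericalError):
    """Null-model randomization cannot move: no swappable 2x2 submatrix."""
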