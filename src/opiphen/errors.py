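"""Exception types shared across the pipeline."""


class OpiphenError(Exception):
    """Base class for all package errors."""


class ConfigError(OpiphenError):
    """An invalid configuration value; the message names the offending field."""


class DataError(OpiphenError):
    """Malformed or inconsistent input records (e.g. negative days' supply)."""


class SchemaError(OpiphenError):
    """A table or matrix is missing a required column; the message names it."""


class ConvergenceError(OpiphenError):
    """An iterative fit failed to reach tolerance; carries diagnostics."""


class CutpointError(OpiphenError):
    """A requested cut-point target is unattainable on the training data."""
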