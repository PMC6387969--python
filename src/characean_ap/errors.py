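"""Exception hierarchy."""


class CharaceanAPError(Exception):
    """Base class for package errors."""


class ArgumentError(CharaceanAPError, ValueError):
    """Invalid argument value (negative rate, nonpositive concentration, ...)."""


class IntegrationError(CharaceanAPError, RuntimeError):
    """ODE solver failed; message carries time of failure and state snapshot."""


class RootFindingError(CharaceanAPError, RuntimeError):
    """Zero-current PD bracket does not contain a sign change."""


class FormatError(CharaceanAPError, ValueError):
    """Malformed trace file (non-uniform grid, bad field, wrong header)."""


class SchemaError(CharaceanAPError, ValueError):
    """Parameter-set file violates the schema (unknown or missing field)."""


class UnknownColumnError(CharaceanAPError, KeyError):
    """Requested registry table/column does not exist."""
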