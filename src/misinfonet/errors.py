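"""Exception hierarchy shared across the package."""


class MisinfonetError(Exception):
    """Base class for package errors."""


class ConfigurationError(MisinfonetError, ValueError):
    """Invalid configuration object or parameter value."""


class StreamFormatError(MisinfonetError, ValueError):
    """Malformed or unsupported stream input."""


class DegenerateDataError(MisinfonetError, ValueError):
    """Data carries no usable variation (e.g. all values identical)."""


class InsufficientTailError(MisinfonetError, ValueError):
    """Too few observations above every candidate cutoff."""


class InsufficientHistoryError(MisinfonetError, ValueError):
    """Node history too short for the requested fit."""


class UndefinedProfileError(MisinfonetError, ValueError):
    """Requested profile is undefined on this snapshot (e.g. no edges)."""
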