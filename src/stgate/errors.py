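"""Exception hierarchy shared across the package."""


class STGateError(Exception):
    """Base class for package errors."""


class ConfigurationError(STGateError):
    """Invalid configuration: bad band edges, shapes, unknown keys, etc."""


class DataError(STGateError):
    """Invalid data: non-finite samples, label mismatches, corrupt stores."""
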