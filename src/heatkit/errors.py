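"""Exception hierarchy shared across the package."""


class HeatkitError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HeatkitError):
    """Invalid configuration: bad year range, missing parameters, etc."""


class DataError(HeatkitError):
    """Invalid or inconsistent data: misaligned dates, empty windows, etc."""


class InsufficientDataError(DataError):
    """Too few observations for the requested statistic."""
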