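"""Exception hierarchy.

ConfigurationError maps to CLI exit code 2, DataError to exit code 3.
"""


class DimrError(Exception):
    """Base class for package errors."""


class ConfigurationError(DimrError):
    """Invalid configuration: unknown measure, bad schema, missing metadata."""


class DataError(DimrError):
    """Invalid or inconsistent input data."""
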