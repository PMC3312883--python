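"""Exception hierarchy.

The CLI maps these onto exit codes: ConfigError -> 2, DataError (and its
subclasses) -> 3.
"""


class ProtlabelError(Exception):
    """Base class for all package errors."""


class ConfigError(ProtlabelError):
    """Invalid configuration, architecture or hyperparameter."""


class DataError(ProtlabelError):
    """Invalid or inconsistent input data."""


class FormatError(DataError):
    """A file does not follow its declared format."""


class AlignmentError(DataError):
    """Two per-residue objects that must align position-by-position do not."""
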