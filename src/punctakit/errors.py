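"""Exception hierarchy shared across the package.

Exit-code mapping used by the command-line layer: parameter problems are
exit code 2, data/schema/metadata problems are exit code 3.
"""


class PunctakitError(Exception):
    """Base class for all package errors."""


class ParameterError(PunctakitError, ValueError):
    """An argument violates a documented precondition."""


class SchemaError(PunctakitError, ValueError):
    """A tabular input does not follow the required column schema."""


class MetadataError(PunctakitError, ValueError):
    """Required image metadata (voxel size) is missing or inconsistent."""


class UnsupportedFormatError(PunctakitError, ValueError):
    """The image file is not a grayscale multi-page stack."""


class PackingError(PunctakitError, RuntimeError):
    """A synthetic placement problem is infeasible at the requested density."""
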