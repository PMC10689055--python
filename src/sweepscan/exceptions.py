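"""Exception hierarchy shared across the package."""


class SweepscanError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SweepscanError, ValueError):
    """Malformed input file (VCF, GFF3, population map, table)."""


class MissingSampleError(SweepscanError, KeyError):
    """A requested sample id is absent from the data."""


class ParameterError(SweepscanError, ValueError):
    """Invalid or inconsistent configuration parameter."""


class StageError(SweepscanError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
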