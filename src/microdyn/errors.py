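"""Exception hierarchy for microdyn."""


class MicrodynError(Exception):
    """Base class for all microdyn errors."""


class FormatError(MicrodynError):
    """A file could not be read under the requested format."""


class StructureError(MicrodynError):
    """A file parsed but its internal structure is inconsistent."""


class ParameterError(MicrodynError, ValueError):
    """An argument violates a precondition."""


class BoundsError(MicrodynError, IndexError):
    """A requested window falls outside the available data."""


class EmptyResultError(MicrodynError):
    """An operation produced no usable output (e.g. no GFP peaks found)."""


class DegenerateInputError(MicrodynError):
    """Input is too degenerate for the statistic to be defined."""


class AssemblyError(MicrodynError):
    """A feature table could not be assembled; names subject and feature."""
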