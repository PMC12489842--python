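"""Exception hierarchy.

Every error raised by the toolkit derives from :class:`SubstrateGraftError`
so callers (and the CLI) can distinguish toolkit failures from bugs.
"""


class SubstrateGraftError(Exception):
    """Base class for all toolkit errors."""


class ParseError(SubstrateGraftError):
    """A structure file could not be parsed."""


class FormatError(SubstrateGraftError):
    """Unknown or unsupported file format."""


class SerializationError(SubstrateGraftError):
    """A structure cannot be written in the requested format."""


class NetworkError(SubstrateGraftError):
    """A remote structure could not be retrieved and is not cached."""


class SelectionError(SubstrateGraftError):
    """A selector resolved to the wrong number of components."""


class ClassificationError(SubstrateGraftError):
    """A residue is not the kind of chemical component the operation needs."""


class InputError(SubstrateGraftError):
    """Operation preconditions on the input data are violated."""


class GeometryError(SubstrateGraftError):
    """Degenerate or chemically impossible geometry."""


class DataError(SubstrateGraftError):
    """Required atoms or coordinates are missing."""


class MappingError(SubstrateGraftError):
    """No atom correspondence could be established between two ligands."""


class ConvergenceError(SubstrateGraftError):
    """Iterative superposition rejected every residue pair."""


class AnnotationError(SubstrateGraftError):
    """Sequence/structure motif annotation failed."""


class ConstructionError(SubstrateGraftError):
    """A synthetic fixture plan is geometrically infeasible."""
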