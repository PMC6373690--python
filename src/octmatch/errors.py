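"""Exception hierarchy for octmatch.

Everything raised on bad user input derives from :class:`OctmatchError`
(and from :class:`ValueError`, so callers who do not care about the finer
distinctions can catch the builtin).
"""


class OctmatchError(Exception):
    """Base class for all octmatch errors."""


class SizeMismatchError(OctmatchError, ValueError):
    """Two point sets that must correspond have different lengths."""


class DegenerateGeometryError(OctmatchError, ValueError):
    """Zero-length bond arms, collinear frames, ill-posed superpositions."""


class ParameterError(OctmatchError, ValueError):
    """A numeric parameter is outside its admissible range."""


class OutOfBoundsError(OctmatchError, ValueError):
    """A point falls outside the octree root cube or loop lattice."""


class ConfigurationError(OctmatchError, ValueError):
    """Co-searched structures were built with incompatible parameters."""


class IncompleteInputError(OctmatchError, ValueError):
    """An operation is missing one of its required inputs."""


class InsufficientSitesError(OctmatchError, ValueError):
    """A scaffold offers fewer take-off sites than the pattern needs."""


class EmptyGridError(OctmatchError, ValueError):
    """A dihedral grid has an empty sample set for some bond."""


class PDBParseError(OctmatchError, ValueError):
    """A coordinate file could not be parsed."""
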