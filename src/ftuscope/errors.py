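"""Exception hierarchy shared across the toolkit."""


class FTUScopeError(Exception):
    """Base class for all ftuscope errors."""


class VocabularyError(FTUScopeError):
    """Invalid controlled-vocabulary configuration or failed term lookup."""


class SchemaError(FTUScopeError):
    """A GeoJSON file or record does not follow the documented schema."""


class GeometryError(FTUScopeError):
    """A polygon is degenerate, self-crossing, or otherwise unusable."""


class BackendContractError(FTUScopeError):
    """A segmentation backend violated its output contract for a tile."""


class CoverageError(FTUScopeError):
    """A tiling plan or tile-mask set leaves part of the canvas unassigned."""


class CapacityError(FTUScopeError):
    """The synthetic generator could not place the requested structures."""
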