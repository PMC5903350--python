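"""Exception hierarchy.

Every error a caller can usefully catch derives from :class:`AngioMVDError`;
subclasses also derive from the closest builtin so generic handlers keep
working (e.g. ``BoundsError`` is an ``IndexError``).
"""


class AngioMVDError(Exception):
    """Base class for all package errors."""


class FormatError(AngioMVDError, ValueError):
    """A file does not conform to its declared format or metadata."""


class UnsupportedMetadataError(FormatError):
    """Header metadata the package refuses to interpret (e.g. anisotropic spacing)."""


class BoundsError(AngioMVDError, IndexError):
    """A VOI or slice index falls outside its parent volume."""


class SamplingError(AngioMVDError, ValueError):
    """Random VOI placement is infeasible under the stated constraints."""


class GeometryError(AngioMVDError, ValueError):
    """Projection geometry is invalid (non-square slices, too few angles)."""


class ParameterError(AngioMVDError, ValueError):
    """An algorithm parameter is outside its valid range."""


class DegenerateInputError(AngioMVDError, ValueError):
    """Input is degenerate for the requested operation (e.g. constant volume for Otsu)."""


class FrameError(AngioMVDError, ValueError):
    """Two objects that must share a volume frame do not."""


class SpecError(AngioMVDError, ValueError):
    """A synthetic-tree specification is internally infeasible."""
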