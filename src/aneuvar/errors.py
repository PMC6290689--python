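"""Exception hierarchy for the analysis pipeline.

Every failure mode that the pipeline is contracted to detect gets its own
class so callers (and the CLI's log-and-continue loop) can react per entry.
"""


class AneuvarError(Exception):
    """Base class for all package errors."""


class FieldMissingError(AneuvarError):
    """A required named vertex field (e.g. ``wss``) is absent from a mesh."""


class UnsupportedCellError(AneuvarError):
    """A polydata file contains cells other than triangles."""


class PlanarityError(AneuvarError):
    """Cross-section points deviate from a common plane beyond tolerance."""


class VelocityAmbiguityError(AneuvarError):
    """A section carries both or neither of vector / magnitude velocity data."""


class DuplicateKeyError(AneuvarError):
    """A metrics table holds more than one value for a (team, case, parameter)."""


class EmptyRegionError(AneuvarError):
    """Clipping removed the entire surface."""


class SeedPointError(AneuvarError):
    """The region seed point lies on the discarded side of a clip plane."""


class EmptySectionError(AneuvarError):
    """A cutting plane does not intersect the mesh."""


class SectionTopologyError(AneuvarError):
    """Plane-mesh intersection segments do not chain into closed loops."""


class DegeneratePatchError(AneuvarError):
    """A cross-section patch has zero area."""


class NormalizationError(AneuvarError):
    """Parent-artery WSS used for normalization is not positive."""


class InsufficientDataError(AneuvarError):
    """Too few values for the requested statistic."""


class GeometryGenerationError(AneuvarError):
    """The synthetic generator was asked for an inconsistent geometry."""
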