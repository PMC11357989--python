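"""Exception hierarchy shared across the package."""


class MorphoHeartError(Exception):
    """Base class for all package-specific errors."""


class MeshFormatError(MorphoHeartError):
    """A mesh file exists but does not conform to the declared format."""


class TopologyError(MorphoHeartError):
    """A mesh violates a topological precondition (open, multi-component, wrong genus...)."""


class GeometryError(MorphoHeartError):
    """A geometric precondition failed (e.g. shell too thick, lips not on boundary)."""


class DegenerateInputError(MorphoHeartError):
    """Input configuration is degenerate (collinear points, coplanar landmarks...)."""


class ParameterError(MorphoHeartError):
    """An invalid parameter value was supplied."""


class LandmarkError(MorphoHeartError):
    """A required named landmark is missing or invalid."""


class ConsistencyError(MorphoHeartError):
    """Correspondences / point sets that should agree in size or identity do not."""


class NoPathError(MorphoHeartError):
    """No path exists between the requested vertices."""


class AmbiguityError(MorphoHeartError):
    """A query has no unique answer (e.g. landmarks project to different boundary loops)."""


class CutError(MorphoHeartError):
    """A requested mesh cut path is invalid."""


class SplitError(MorphoHeartError):
    """A plane split left one side empty."""


class AnisotropyError(MorphoHeartError):
    """A vertex region is too isotropic for a principal direction to be meaningful."""
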