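"""Exception hierarchy.

Error messages deliberately contain stable key phrases (e.g. "empty patch",
"non-manifold mesh") so callers and tests can match on them.
"""


class FasciTraceError(Exception):
    """Base class for all package errors."""


class MeshFormatError(FasciTraceError):
    """Unreadable or unsupported mesh file content."""


class MeshTopologyError(FasciTraceError):
    """Invalid mesh topology or geometry (degenerate / non-manifold)."""


class PatchError(FasciTraceError):
    """Invalid boundary-patch selection or seeding request."""


class BoundaryConditionError(FasciTraceError):
    """Boundary-flux specification violates a precondition."""


class SolverError(FasciTraceError):
    """Linear solve or flux-field consistency failure."""


class TracingError(FasciTraceError):
    """Streamline tracing failure."""


class TractError(FasciTraceError):
    """Tract post-processing failure."""


class ConfigError(FasciTraceError):
    """Invalid run configuration."""
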