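"""Exception hierarchy for spinekit."""


class SpinekitError(Exception):
    """Base class for all spinekit errors."""


class MeshFormatError(SpinekitError):
    """A mesh file could not be parsed in the requested dialect."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" in {path}"
        if line is not None:
            loc += f" at line {line}"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class EmptyMeshError(SpinekitError):
    """A mesh file parsed but contained no usable geometry."""


class InvalidMeshError(SpinekitError):
    """A mesh violates the triangle-mesh invariants."""


class NotWatertightError(SpinekitError):
    """An operation requiring a closed surface got an open mesh."""

    def __init__(self, boundary_edges: int):
        super().__init__(
            f"mesh is not watertight: {boundary_edges} boundary edge(s)"
        )
        self.boundary_edges = boundary_edges


class AttachmentError(SpinekitError):
    """The supplied attachment point is too far from the mesh surface."""


class ProfileError(SpinekitError):
    """Cross-section profiling failed at too many stations."""


class SchemaError(SpinekitError):
    """A tabular file does not match the expected schema."""


class QueryError(SpinekitError):
    """A retrieval query is malformed or cannot be evaluated."""


class SimulationError(SpinekitError):
    """The compartmental integrator failed or diverged."""
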