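"""Exception types shared across the pipeline stages."""


class PrintQAError(Exception):
    """Base class for all printqa errors."""


class NotWatertightError(PrintQAError):
    """A solid operation was requested on a mesh with open edges."""

    def __init__(self, n_open_edges: int, context: str = "mesh"):
        self.n_open_edges = n_open_edges
        super().__init__(
            f"{context} is not watertight: {n_open_edges} edge(s) are not "
            f"shared by exactly two faces"
        )


class STLFormatError(PrintQAError):
    """Malformed or truncated STL file."""


class EmptySegmentationError(PrintQAError):
    """No voxel reaches the requested threshold (or the iso-surface is degenerate)."""


class GridTooSmallError(PrintQAError):
    """The requested voxel grid does not contain the mesh plus the PSF margin."""


class MisalignmentError(PrintQAError):
    """ICP terminated with a residual too large for a trustworthy comparison."""


class SelfIntersectionError(PrintQAError):
    """A print-deformation spec would fold the surface into itself."""
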