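"""Exception hierarchy.

Every error raised by the library derives from :class:`FluctuogramError`
so callers (and the CLI) can map categories to exit codes.
"""


class FluctuogramError(Exception):
    """Base class for all library errors."""


class FormatError(FluctuogramError):
    """A file could not be parsed as the expected format."""


class StructureError(FluctuogramError):
    """An atomic structure violates a coarse-graining precondition."""


class GeometryError(FluctuogramError):
    """A network geometry is degenerate (fewer rigid-body modes than expected)."""


class DisconnectedNetworkError(FluctuogramError):
    """The elastic network splits into disconnected components.

    The offending components (lists of site ids) are stored in
    ``components``.
    """

    def __init__(self, components):
        self.components = [sorted(c) for c in components]
        super().__init__(
            f"elastic network is disconnected: {len(self.components)} components "
            f"{self.components}"
        )


class RosterMismatchError(FluctuogramError):
    """Two objects that must share a site/residue roster do not."""


class ZeroVarianceError(FluctuogramError):
    """A bond shows zero fluctuation, so its force constant is undefined."""
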