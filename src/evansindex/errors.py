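"""Exception hierarchy with machine-readable categories for the CLI."""


class EvansIndexError(Exception):
    """Base class; ``category`` feeds the CLI's structured error output."""

    category = "GEOMETRY"


class InputError(EvansIndexError):
    """Missing files, malformed headers, mismatched grids, bad arguments."""

    category = "IO"


class GeometryError(EvansIndexError):
    """Implausible or degenerate geometry (oblique affine, reversed AC/PC, EI out of range)."""

    category = "GEOMETRY"


class EmptyMaskError(EvansIndexError):
    """An operation that requires foreground voxels received none."""

    category = "EMPTY_MASK"
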