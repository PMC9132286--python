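"""Exception types shared across the package."""


class FlexiscreenError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(FlexiscreenError):
    """A PDB record could not be parsed."""


class TopologyError(FlexiscreenError):
    """Frames of an ensemble do not share one topology."""


class TableParseError(FlexiscreenError):
    """A tabular fixture (design / region / ΔRMSF table) is malformed."""


class DegenerateGeometryError(FlexiscreenError):
    """A coordinate set is too degenerate for superposition."""
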