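"""Exception hierarchy.

Every error raised on purpose by this package derives from ConfeError so
callers can catch package failures without masking programming errors.
"""


class ConfeError(Exception):
    """Base class for all package errors."""


class PDBParseError(ConfeError):
    """A PDB record could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class TopologyError(ConfeError):
    """Missing or inconsistent topology data (sections, parameters, bonds)."""


class SelectionError(ConfeError):
    """Selection expression syntax error; carries the character position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"position {position}: {message}"
        super().__init__(message)


class GeometryError(ConfeError):
    """Degenerate geometry: collinear fits, undefined dihedrals, etc."""


class EnergyError(ConfeError):
    """Energy evaluation failure (missing parameters, shape mismatch)."""


class EnsembleError(ConfeError):
    """Invalid ensemble: empty, mismatched atom counts, NaN coordinates."""


class ConfigError(ConfeError):
    """Invalid run configuration; message names the offending field path."""
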