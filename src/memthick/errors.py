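"""Exception and warning types shared across the package."""


class MemthickError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MemthickError):
    """A coordinate file line could not be parsed.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class StructureError(MemthickError):
    """The parsed file is well-formed line-by-line but structurally invalid
    (e.g. inconsistent bead counts across frames, missing box)."""


class GeometryError(MemthickError):
    """A geometric construction is impossible (lattice too small,
    degenerate selection for superposition, zero axis vector, ...)."""


class SelectionError(MemthickError):
    """A selection query is invalid for the given system."""


class FitError(MemthickError):
    """A density-profile fit could not be initialized or used."""


class EmptySelectionWarning(UserWarning):
    """A selection query matched no beads.

    The empty selection is still returned so callers can decide how to
    proceed, but it is never produced silently.
    """
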