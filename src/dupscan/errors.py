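"""Exception hierarchy for dupscan.

Every error raised by the library derives from :class:`DupscanError` so that
callers (and the CLI) can catch the whole family at once.
"""


class DupscanError(Exception):
    """Base class for all dupscan errors."""


class DegenerateFrame(DupscanError):
    """Frame atoms coincide or are collinear; no local basis exists."""

    def __init__(self, message: str, residue_index: int | None = None):
        super().__init__(message)
        self.residue_index = residue_index


class ImproperRotation(DupscanError):
    """Matrix is not a proper rotation (not orthogonal or det != +1)."""


class LengthMismatch(DupscanError):
    """Two point sets / chains that must have equal length do not."""


class TooFewPoints(DupscanError):
    """Superposition needs at least three point pairs."""


class DimensionMismatch(DupscanError):
    """Invariant matrices of different shapes cannot be compared."""


class ChainTooShort(DupscanError):
    """A backbone needs at least two residues to carry an invariant."""


class InvalidRowOne(DupscanError):
    """First invariant row violates the canonical zero pattern."""


class BadMode(DupscanError):
    """Unknown duplicate-generation mode."""


class DegenerateGeometry(DupscanError):
    """Synthetic-backbone geometry parameters produce degenerate residues."""


class ParseError(DupscanError):
    """A structure file could not be parsed."""


class UnsupportedFormat(DupscanError):
    """File format not recognized as PDB or mmCIF."""


class MissingResolution(DupscanError):
    """Entry metadata carries no resolution; scoping cannot be decided."""
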