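"""Named failure types raised throughout the package.

Every precondition violation maps to a distinct exception class so callers
(and the CLI) can report module-qualified errors instead of bare ValueErrors.
"""


class EpiscanError(Exception):
    """Base class for all package-specific failures."""


class FastaFormatError(EpiscanError):
    """Malformed FASTA input: bad header, blank record, no records."""


class IllegalResidueError(EpiscanError):
    """A sequence character is outside the declared alphabet."""

    def __init__(self, message: str, record_id: str = "", position: int = 0):
        super().__init__(message)
        self.record_id = record_id
        self.position = position  # 1-based


class AlignmentLengthError(EpiscanError):
    """Gapped records in an alignment do not share a common length."""


class InvalidIUPACCodeError(EpiscanError):
    """A primer character is not a valid IUPAC nucleotide code."""


class WindowError(EpiscanError):
    """Sliding-window request incompatible with the sequence (too long, even, ...)."""


class SequenceTooShortError(EpiscanError):
    """Sequence shorter than the minimum length an operation requires."""


class ScaleError(EpiscanError):
    """Residue scale file malformed, incomplete, or used in the wrong mode."""


class ParamTableError(EpiscanError):
    """Secondary-structure parameter table missing entries or malformed."""


class TrackLengthError(EpiscanError):
    """Per-residue tracks that must be aligned have different lengths or ids."""


class WeightError(EpiscanError):
    """Component weights violate their contract (negative, wrong sum, wrong count)."""


class ThresholdError(EpiscanError):
    """Discretization thresholds are non-monotone or mismatched with score levels."""


class CriteriaError(EpiscanError):
    """Selection criteria are internally inconsistent or out of bounds."""


class RegionError(EpiscanError):
    """A 1-based inclusive interval is empty or outside the coordinate bounds."""


class GroupLabelError(EpiscanError):
    """Group-wise analysis requested but group labels are missing or degenerate."""


class SyntheticSpecError(EpiscanError):
    """Synthetic-data specification invalid (overlapping segments, bad rate, ...)."""


class ChecksumError(EpiscanError):
    """A packaged parameter file does not match its pinned checksum."""
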