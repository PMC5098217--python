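"""Exception and warning types shared across the package."""


class ExodelError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(ExodelError, ValueError):
    """A synthetic-fragment specification violates its own invariants."""


class InfeasibleDesignError(ExodelError, ValueError):
    """A digestion/ladder design cannot satisfy the read-overlap constraint."""


class OrientationUndecidableError(ExodelError):
    """The restriction banding pattern cannot distinguish the two insert
    orientations (site absent from the insert, or symmetrically placed)."""


class NoOverlapError(ExodelError):
    """No offset hypothesis reaches the minimum overlap between two reads."""


class InconsistentSizeError(ExodelError):
    """An externally supplied exact deletion size matches none of the tied
    offset hypotheses."""


class UnplaceableReadError(ExodelError):
    """Neither orientation of a read overlaps its neighbour above threshold."""


class AccessionFetchError(ExodelError):
    """A remote sequence record could not be retrieved (offline, malformed
    identifier, or malformed record)."""


class GapInLadderWarning(UserWarning):
    """The molecule pool is too sparse to maintain the requested ladder
    spacing; the message names the uncovered size interval."""
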