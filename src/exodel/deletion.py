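"""In-silico model of the nested-deletion wet lab.

The pipeline this module simulates: a repeat-rich fragment is excised with
two restriction enzymes that leave a protected end (4-base 3' overhang,
refractory to exonuclease III) and an unprotected end (blunt / 5'
protruding, a substrate).  Timed exonuclease III digestion then removes
bases from the unprotected end only, at ~450 bp/min at 37 degC, producing a
pool of molecules with widely dispersed deletion depths.  Aliquots taken at
staggered times, gel size selection at ~400 bp spacing, orientation calling
by restriction banding, and one vector-primer Sanger read per selected
clone complete the simulated experiment.

Coordinate convention
---------------------
Construct coordinates run *from the unprotected end*: position 0 is the
unprotected cut, digestion removes a prefix, and the protected end is the
right end of the string.  A clone with deletion ``d`` retains
``construct.sequence[d:]`` and its read covers ``sequence[d : d + read_len]``.
This may be the reverse complement of the biological top strand; in silico
the choice is immaterial and it makes reads, offsets and the assembly all
run left to right.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (GapInLadderWarning, InfeasibleDesignError,
                     OrientationUndecidableError)
from .repeats import BASES, AnnotatedSequence, reverse_complement

__all__ = [
    "Construct",
    "DigestionSchedule",
    "DeletionMolecule",
    "CloneLadder",
    "LadderEntry",
    "SangerRead",
    "ReadLengthModel",
    "PlannedDesign",
    "plan_digestion_schedule",
    "simulate_exonuclease_digestion",
    "simulate_gel_size_selection",
    "call_orientation",
    "simulate_sanger_read",
    "restriction_bands",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def _pattern_regex(pattern: str) -> re.Pattern[str]:
    try:
        return re.compile("".join(_IUPAC[b] for b in pattern.upper()))
    except KeyError as exc:  # pragma: no cover - input validation
        raise ValueError(f"non-IUPAC symbol in recognition pattern: {exc}") from exc


@dataclass
class Construct:
    """The linearized fragment between the two restriction cuts.

    ``unprotected_pad`` (87 bp in the reference design) sits between the
    blunt cut and the insert; ``protected_pad`` (8 bp) between the insert
    and the protective cut.  ``sequence`` = unprotected_pad + insert +
    protected_pad, with digestion entering from the left.
    """

    insert: AnnotatedSequence
    unprotected_pad: str = ""
    protected_pad: str = ""
    protected_end: str = "three_prime_overhang"
    unprotected_end: str = "blunt"

    def __post_init__(self) -> None:
        if self.protected_end != "three_prime_overhang":
            raise ValueError("only a 3' overhang protected end is modelled")
        if self.unprotected_end not in ("blunt", "five_prime_protruding"):
            raise ValueError("unprotected end must be blunt or 5' protruding")

    @classmethod
    def from_insert(cls, insert: AnnotatedSequence,
                    unprotected_offset: int = 87, protected_offset: int = 8,
                    seed: int = 0) -> "Construct":
        """Build a construct with random vector-derived pad sequence."""
        rng = np.random.default_rng(seed)
        pads = rng.integers(0, 4, size=unprotected_offset + protected_offset)
        letters = np.array(list(BASES))
        pad = "".join(letters[pads])
        return cls(insert, unprotected_pad=pad[:unprotected_offset],
                   protected_pad=pad[unprotected_offset:])

    @property
    def sequence(self) -> str:
        return self.unprotected_pad + self.insert.sequence + self.protected_pad

    @property
    def insert_start(self) -> int:
        return len(self.unprotected_pad)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DigestionSchedule:
    """Timed-aliquot plan for the exonuclease III digestion.

    Defaults follow the reference protocol: 450 bp/min at 37 degC, first
    aliquot at 2 min, each further aliquot 90 s longer, three aliquots.
    """

    rate_bp_per_min: float = 450.0
    first_time_s: float = 120.0
    increment_s: float = 90.0
    n_aliquots: int = 3

    def __post_init__(self) -> None:
        if min(self.rate_bp_per_min, self.first_time_s, self.increment_s) <= 0:
            raise ValueError("rate and times must be positive")
        if self.n_aliquots < 1:
            raise ValueError("need at least one aliquot")

    def time_s(self, aliquot: int) -> float:
        """Digestion time of 0-based ``aliquot``."""
        return self.first_time_s + aliquot * self.increment_s

    def expected_depth_bp(self, aliquot: int) -> float:
        """Mean deletion depth of ``aliquot``: rate x time."""
        return self.rate_bp_per_min * self.time_s(aliquot) / 60.0

    @property
    def times_s(self) -> list[float]:
        return [self.time_s(k) for k in range(self.n_aliquots)]


@dataclass(frozen=True)
class DeletionMolecule:
    """One digestion product: ``true_deletion_bp`` bases removed from the
    unprotected end.  The remaining sequence is materialized lazily from the
    construct to keep large pools cheap."""

    true_deletion_bp: int
    aliquot_index: int
    construct: Construct = field(repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.true_deletion_bp < len(self.construct)):
            raise ValueError("deletion must leave at least one base")

    @property
    def remaining_length(self) -> int:
        return len(self.construct) - self.true_deletion_bp

    @property
    def remaining_sequence(self) -> str:
        return self.construct.sequence[self.true_deletion_bp:]


@dataclass
class LadderEntry:
    molecule: DeletionMolecule
    estimated_size_bp: float
    orientation: str  # "forward" | "reverse"


@dataclass
class CloneLadder:
    """Size-selected clones ordered from largest (least deleted) to
    smallest; consecutive estimated sizes differ by ~``target_spacing_bp``."""

    selected: list[LadderEntry]
    target_spacing_bp: float
    size_noise_sd_bp: float
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.selected)

    @property
    def estimated_sizes(self) -> list[float]:
        return [e.estimated_size_bp for e in self.selected]

    @property
    def estimated_offsets(self) -> list[float]:
        """Consecutive estimated size differences = approximate deletion
        offsets handed to the assembler."""
        s = self.estimated_sizes
        return [s[i] - s[i + 1] for i in range(len(s) - 1)]

    @property
    def true_deletions(self) -> list[int]:
        return [e.molecule.true_deletion_bp for e in self.selected]


@dataclass(frozen=True)
class SangerRead:
    """A single vector-primer read from one clone, starting exactly at the
    deleted end and running toward the protected end.

    ``sequence`` is as reported by the sequencer: reverse-complemented when
    the clone was inserted in reverse orientation, so downstream orientation
    handling is exercised."""

    sequence: str
    source_clone_index: int
    orientation: str = "forward"
    error_rate: float = 0.0

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadLengthModel:
    """Sanger read-length distribution: normal(mean, sd) clipped to
    [min, max]; ``fixed`` short-circuits to a constant length."""

    mean: float = 700.0
    sd: float = 60.0
    minimum: int = 550
    maximum: int = 900
    fixed: int | None = None

    def sample(self, rng: np.random.Generator) -> int:
        if self.fixed is not None:
            return int(self.fixed)
        draw = rng.normal(self.mean, self.sd)
        return int(np.clip(round(draw), self.minimum, self.maximum))


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlannedDesign:
    """Output of :func:`plan_digestion_schedule`: the schedule plus the
    predicted ladder geometry."""

    schedule: DigestionSchedule
    min_clones: int
    expected_overlap_bp: float
    aliquot_depth_ranges: list[tuple[float, float, float]]  # (lo, mean, hi)


def plan_digestion_schedule(fragment_len_bp: int,
                            rate_bp_per_min: float = 450.0,
                            target_spacing_bp: float = 400.0,
                            read_len_bp: float = 500.0,
                            first_time_s: float = 120.0,
                            increment_s: float = 90.0,
                            dispersion_shape: float = 1.2,
                            coverage_quantile: float = 0.99,
                            min_overlap_bp: float = 100.0) -> PlannedDesign:
    """Plan the number of timed aliquots and the minimum clone count.

    The number of aliquots is the smallest ``n`` such that the union of
    per-aliquot plausible deletion-depth ranges (central
    ``coverage_quantile`` mass of the Gamma dispersion model, with the first
    aliquot's range anchored at 0) spans ``[0, fragment_len_bp]``.

    ``min_clones`` is the tiling bound ``ceil((L - read_len) / spacing) + 1``:
    consecutive reads shifted by the ladder spacing, plus the undeleted
    full-length clone.

    Raises :class:`InfeasibleDesignError` when ``read_len_bp -
    target_spacing_bp < min_overlap_bp`` -- consecutive reads would not
    overlap enough to be joined.
    """
    overlap = read_len_bp - target_spacing_bp
    if overlap < min_overlap_bp:
        raise InfeasibleDesignError(
            f"read length {read_len_bp} bp minus ladder spacing "
            f"{target_spacing_bp} bp leaves {overlap:.0f} bp of overlap; "
            f"at least {min_overlap_bp:.0f} bp is required to join "
            f"consecutive reads"
        )
    min_clones = int(np.ceil((fragment_len_bp - read_len_bp) / target_spacing_bp)) + 1

    q_lo = (1.0 - coverage_quantile) / 2.0
    q_hi = 1.0 - q_lo
    ranges: list[tuple[float, float, float]] = []
    n = 0
    covered_to = 0.0
    while True:
        n += 1
        t = first_time_s + (n - 1) * increment_s
        mean = rate_bp_per_min * t / 60.0
        theta = mean / dispersion_shape
        lo = float(stats.gamma.ppf(q_lo, dispersion_shape, scale=theta))
        hi = float(stats.gamma.ppf(q_hi, dispersion_shape, scale=theta))
        if n == 1:
            lo = 0.0  # digestion depths start at a few bases
        ranges.append((lo, mean, hi))
        if lo > covered_to:
            # a gap between aliquot ranges: denser time points are needed
            raise InfeasibleDesignError(
                f"aliquot {n} plausible depths start at {lo:.0f} bp but "
                f"coverage only reaches {covered_to:.0f} bp; reduce the "
                f"time increment"
            )
        covered_to = max(covered_to, hi)
        if covered_to >= fragment_len_bp:
            break
        if n > 1000:  # pragma: no cover - defensive
            raise InfeasibleDesignError("cannot cover fragment with <=1000 aliquots")

    schedule = DigestionSchedule(rate_bp_per_min=rate_bp_per_min,
                                 first_time_s=first_time_s,
                                 increment_s=increment_s, n_aliquots=n)
    return PlannedDesign(schedule=schedule, min_clones=min_clones,
                         expected_overlap_bp=overlap,
                         aliquot_depth_ranges=ranges)


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------


def simulate_exonuclease_digestion(construct: Construct,
                                   schedule: DigestionSchedule,
                                   n_molecules: int = 9000,
                                   dispersion_shape: float = 1.2,
                                   seed: int | np.random.Generator = 0,
                                   ) -> list[DeletionMolecule]:
    """Draw a pool of deletion molecules from timed exonuclease digestion.

    Deletion depth of a molecule in aliquot ``k`` is Gamma distributed with
    mean ``rate x time_k`` and shape ``dispersion_shape``; the default shape
    of 1.2 reproduces the observed spread from a few bases (5th percentile
    under 100 bp at 2 min) to more than 2000 bp at 2-5 min digestion.  Digestion is strictly unidirectional --
    the protected 3'-overhang end never loses a base -- and molecules whose
    deletion reaches the protected site are degraded and excluded from the
    returned pool.

    ``n_molecules`` is split evenly across aliquots.  Zero digestion time
    would yield zero deletions; the schedule forbids it, but a depth drawn
    as 0 is legal (deletion of 0 bp).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    length = len(construct)
    per = [n_molecules // schedule.n_aliquots] * schedule.n_aliquots
    for i in range(n_molecules - sum(per)):
        per[i] += 1
    pool: list[DeletionMolecule] = []
    for k in range(schedule.n_aliquots):
        mean = schedule.expected_depth_bp(k)
        if mean <= 0:
            depths = np.zeros(per[k])
        else:
            depths = rng.gamma(dispersion_shape, mean / dispersion_shape,
                               size=per[k])
        for d in depths:
            d = int(round(d))
            if d >= length:
                continue  # degraded into the protected site: lost
            pool.append(DeletionMolecule(d, k, construct))
    return pool


# ---------------------------------------------------------------------------
# gel size selection
# ---------------------------------------------------------------------------


def simulate_gel_size_selection(molecules: list[DeletionMolecule],
                                target_spacing_bp: float = 400.0,
                                size_noise_sd_bp: float = 50.0,
                                full_insert_len: int | None = None,
                                seed: int | np.random.Generator = 0,
                                spacing_min_bp: float = 0.0,
                                spacing_max_bp: float | None = None,
                                stop_len_bp: float | None = None,
                                include_full_length: bool = True) -> CloneLadder:
    """Greedy toothpick-assay ladder selection.

    Each molecule's size is estimated with Gaussian gel noise
    (``size_noise_sd_bp``).  Starting from the largest clone (the undeleted
    construct when ``include_full_length``), the next clone is the one whose
    estimated size is closest to ``previous - target_spacing_bp`` among
    candidates within ``[previous - spacing_max, previous - spacing_min]``
    (``spacing_max`` defaults to the target spacing, which caps the true
    spacing at the target when the gel is noise-free).  When no candidate
    falls in the window a gap warning naming the uncovered size interval is
    recorded (and emitted as :class:`GapInLadderWarning`) and selection
    jumps to the nearest smaller clone.  Selection stops once the estimated
    size drops to ``stop_len_bp`` (when given) or the pool is exhausted.

    Cloning orientation is assigned uniformly at random to each selected
    clone; recovering it is the orientation caller's job.
    """
    if not molecules:
        raise ValueError("molecule pool is empty")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if spacing_max_bp is None:
        spacing_max_bp = target_spacing_bp
    construct = molecules[0].construct
    pool = list(molecules)
    full_idx: int | None = None
    if include_full_length:
        # the untreated original clone is known a priori (it is the first
        # gel lane), so it anchors the ladder regardless of size noise
        for i, m in enumerate(pool):
            if m.true_deletion_bp == 0:
                full_idx = i
                break
        if full_idx is None:
            pool.append(DeletionMolecule(0, -1, construct))
            full_idx = len(pool) - 1

    sizes = np.array([m.remaining_length for m in pool], dtype=float)
    est = sizes + (rng.normal(0.0, size_noise_sd_bp, size=len(pool))
                   if size_noise_sd_bp > 0 else 0.0)

    available = np.ones(len(pool), dtype=bool)

    selected: list[LadderEntry] = []
    warn_msgs: list[str] = []

    first = int(np.argmax(est)) if full_idx is None else full_idx
    available[first] = False
    selected.append(LadderEntry(pool[first], float(est[first]),
                                _draw_orientation(rng)))
    current = float(est[first])

    while True:
        if stop_len_bp is not None and current <= stop_len_bp:
            break
        lo, hi = current - spacing_max_bp, current - spacing_min_bp
        target = current - target_spacing_bp
        cand = np.flatnonzero(available & (est >= lo) & (est <= hi) & (est < current))
        if cand.size == 0:
            below = np.flatnonzero(available & (est < current))
            if below.size == 0:
                break
            nxt = int(below[np.argmax(est[below])])
            gap_hi, gap_lo = current, float(est[nxt])
            if gap_hi - gap_lo > spacing_max_bp:
                msg = (f"no clone between estimated sizes "
                       f"[{gap_lo:.0f}, {gap_hi - spacing_min_bp:.0f}) bp; "
                       f"ladder spacing exceeds {spacing_max_bp:.0f} bp")
                warn_msgs.append(msg)
                warnings.warn(msg, GapInLadderWarning, stacklevel=2)
        else:
            nxt = int(cand[np.argmin(np.abs(est[cand] - target))])
        available[nxt] = False
        selected.append(LadderEntry(pool[nxt], float(est[nxt]),
                                    _draw_orientation(rng)))
        current = float(est[nxt])

    return CloneLadder(selected=selected, target_spacing_bp=target_spacing_bp,
                       size_noise_sd_bp=size_noise_sd_bp, warnings=warn_msgs)


def _draw_orientation(rng: np.random.Generator) -> str:
    return "forward" if rng.random() < 0.5 else "reverse"


# ---------------------------------------------------------------------------
# orientation calling by restriction banding
# ---------------------------------------------------------------------------


def restriction_bands(molecule_seq: str, pattern: str) -> tuple[int, ...]:
    """Fragment sizes (sorted) from cutting ``molecule_seq`` at every match
    of the IUPAC ``pattern`` (cut at the match start; in-silico banding only
    needs relative positions)."""
    regex = _pattern_regex(pattern)
    cuts = [m.start() for m in regex.finditer(molecule_seq.upper())]
    if not cuts:
        return (len(molecule_seq),)
    edges = [0] + cuts + [len(molecule_seq)]
    return tuple(sorted(b - a for a, b in zip(edges, edges[1:]) if b > a))


def call_orientation(remaining_sequence: str, true_orientation: str,
                     recognition_pattern: str,
                     left_arm: str, right_arm: str) -> str:
    """Recover a clone's cloning orientation from its restriction banding.

    The simulated assay digests the clone (left vector arm + oriented insert
    + right vector arm) at ``recognition_pattern`` and compares the observed
    band sizes with the patterns predicted for either orientation.  Returns
    ``"forward"`` or ``"reverse"``; deterministic.

    Raises :class:`OrientationUndecidableError` when the two predicted
    patterns coincide (no site in the insert, or sites placed symmetrically)
    -- the caller must then try both orientations downstream.
    """
    fwd = left_arm + remaining_sequence + right_arm
    rev = left_arm + reverse_complement(remaining_sequence) + right_arm
    bands_fwd = restriction_bands(fwd, recognition_pattern)
    bands_rev = restriction_bands(rev, recognition_pattern)
    if bands_fwd == bands_rev:
        raise OrientationUndecidableError(
            "restriction pattern does not distinguish the orientations "
            "(absent from the insert or symmetric)"
        )
    observed = bands_fwd if true_orientation == "forward" else bands_rev
    return "forward" if observed == bands_fwd else "reverse"


# ---------------------------------------------------------------------------
# Sanger reads
# ---------------------------------------------------------------------------


def simulate_sanger_read(entry: LadderEntry, clone_index: int,
                         read_length: ReadLengthModel | int = ReadLengthModel(),
                         error_rate: float = 0.0,
                         seed: int | np.random.Generator = 0) -> SangerRead:
    """One vector-primer read from a ladder clone.

    The read starts exactly at the deleted (unprotected) end and extends
    toward the protected end for ``min(read_len, remaining length)`` bases.
    Substitution errors are i.i.d. at ``error_rate`` (errors are coupled
    across rates: re-simulating with a higher rate at the same seed yields a
    superset of error positions).  The emitted sequence is
    reverse-complemented for reverse-orientation clones.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if isinstance(read_length, int):
        read_length = ReadLengthModel(fixed=read_length)
    remaining = entry.molecule.remaining_sequence
    if not remaining:
        raise ValueError("clone retains no insert to sequence")
    rl = min(read_length.sample(rng), len(remaining))
    span = list(remaining[:rl])
    # draw both the error flags and the substitute choices unconditionally so
    # that error sets are nested across error rates at a fixed seed
    flags = rng.random(rl)
    subs = rng.integers(0, 3, size=rl)
    if error_rate > 0:
        for i in np.flatnonzero(flags < error_rate):
            others = [b for b in BASES if b != span[i]]
            span[i] = others[subs[i]]
    seq = "".join(span)
    if entry.orientation == "reverse":
        seq = reverse_complement(seq)
    return SangerRead(sequence=seq, source_clone_index=clone_index,
                      orientation=entry.orientation, error_rate=error_rate)
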