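"""Synthetic repeat-rich fragments and repeat annotation.

This module generates the two classes of ground-truth sequence the in-silico
sequencing campaign operates on -- long stretches of simple sequence repeats
(SSRs, motif length 1-6 bp) and tandem gene arrays (a short conserved unit
followed by a spacer, repeated head-to-tail) -- and annotates repeat
structure in arbitrary nucleotide sequences.

Conventions
-----------
* All coordinates are 0-based, half-open.
* An SSR run is reported as whole copies of its motif: the annotated
  interval is the longest stretch of complete motif repetitions (isolated
  single-base interruptions allowed), trimmed so its length is a multiple
  of the motif period.  Partial trailing copies are not included in the
  interval.
* Motifs are reported under their canonical rotation (the lexicographically
  least rotation), so AAG / AGA / GAA are one class.  Reverse-complement
  motifs (CTT etc.) are a distinct class; annotation is single-stranded.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSpecError

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

__all__ = [
    "MotifRun",
    "SSRFragmentSpec",
    "TandemArraySpec",
    "AnnotatedSequence",
    "canonical_rotation",
    "smallest_period",
    "reverse_complement",
    "generate_ssr_fragment",
    "generate_tandem_array_fragment",
    "annotate_ssr_runs",
    "continuous_ssr_regions",
    "count_tandem_units",
    "default_ssr_spec",
    "default_tandem_spec",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_rotation(motif: str) -> str:
    """Lexicographically least rotation of ``motif``.

    Collapses the phase ambiguity of a tandem motif: a run of AAG read one
    base later is a run of AGA; both are reported as AAG.
    """
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def smallest_period(motif: str) -> int:
    """Smallest ``p`` such that ``motif`` is a prefix of an infinite
    repetition of ``motif[:p]``; equals ``len(motif)`` for aperiodic motifs."""
    n = len(motif)
    for p in range(1, n):
        if all(motif[i] == motif[i % p] for i in range(n)):
            return p
    return n


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifRun:
    """A tandem run of a short motif.

    Attributes
    ----------
    motif:
        Canonical rotation of the repeated unit (1-6 bp).
    start, end:
        0-based half-open interval of the run on the annotated sequence.
    copy_count:
        Number of (possibly imperfect) motif repetitions; equals
        ``(end - start) // len(motif)``.
    mismatch_positions:
        0-based positions inside ``[start, end)`` whose base departs from
        the pure periodic repeat.
    """

    motif: str
    start: int
    end: int
    copy_count: int
    mismatch_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("run interval must be non-empty")
        if not (1 <= len(self.motif) <= 6):
            raise ValueError("motif period must be 1-6 bp")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SSRFragmentSpec:
    """Recipe for a synthetic SSR-rich fragment.

    ``blocks`` is an ordered list of ``(motif, copy_count)`` pairs laid down
    contiguously (an uninterrupted repeat region) between two random,
    repeat-free flanks.  ``variant_rate`` is the per-base probability of a
    single-base substitution inside the repeat region -- the "anchor"
    variants that make ordered assembly of a near-perfect repeat
    unambiguous.
    """

    total_length: int
    blocks: tuple[tuple[str, int], ...]
    variant_rate: float = 0.01
    flank_lengths: tuple[int, int] = (0, 0)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple((m.upper(), int(c)) for m, c in self.blocks))
        repeat_bp = self.repeat_length
        if repeat_bp + sum(self.flank_lengths) != self.total_length:
            raise InvalidSpecError(
                f"block lengths ({repeat_bp} bp) plus flanks "
                f"({sum(self.flank_lengths)} bp) must equal total_length "
                f"({self.total_length} bp)"
            )
        if not (0.0 <= self.variant_rate <= 0.05):
            raise InvalidSpecError("variant_rate must lie in [0, 0.05]")
        for motif, count in self.blocks:
            if not (1 <= len(motif) <= 6) or set(motif) - set(BASES):
                raise InvalidSpecError(f"bad motif {motif!r}")
            if count < 1:
                raise InvalidSpecError("copy_count must be >= 1")
        for (m1, _), (m2, _) in zip(self.blocks, self.blocks[1:]):
            if canonical_rotation(m1) == canonical_rotation(m2):
                raise InvalidSpecError(
                    "adjacent blocks with the same canonical motif must be merged"
                )

    @property
    def repeat_length(self) -> int:
        return sum(len(m) * c for m, c in self.blocks)

    def spec_hash(self) -> str:
        payload = repr((self.total_length, self.blocks, self.variant_rate,
                        self.flank_lengths, self.seed)).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


@dataclass(frozen=True)
class TandemArraySpec:
    """Recipe for a tandem gene array: ``n_units`` head-to-tail copies of a
    unit made of a conserved coding region (~120 bp for a 5S rRNA-like gene)
    plus a non-transcribed spacer (NTS, 100-700 bp), between random flanks.

    ``per_unit_divergence`` is the per-base substitution probability applied
    independently to every copy relative to the master unit.
    """

    unit_coding_length: int = 120
    nts_length: int = 180
    n_units: int = 15
    per_unit_divergence: float = 0.01
    flank_lengths: tuple[int, int] = (40, 45)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise InvalidSpecError("n_units must be >= 1")
        if not (100 <= self.nts_length <= 700):
            raise InvalidSpecError("nts_length must lie in [100, 700]")
        if self.unit_coding_length < 1:
            raise InvalidSpecError("unit_coding_length must be positive")
        if not (0.0 <= self.per_unit_divergence <= 0.2):
            raise InvalidSpecError("per_unit_divergence must lie in [0, 0.2]")

    @property
    def unit_length(self) -> int:
        return self.unit_coding_length + self.nts_length

    @property
    def total_length(self) -> int:
        return self.unit_length * self.n_units + sum(self.flank_lengths)

    def spec_hash(self) -> str:
        payload = repr((self.unit_coding_length, self.nts_length, self.n_units,
                        self.per_unit_divergence, self.flank_lengths, self.seed)).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


@dataclass
class AnnotatedSequence:
    """A nucleotide sequence plus its known repeat structure.

    For generator output the annotation is the construction truth (every
    planted variant is recorded); for annotator output it is inferred.
    """

    sequence: str
    ssr_runs: list[MotifRun] = field(default_factory=list)
    tandem_units: list[tuple[int, int]] = field(default_factory=list)
    source: str = "unknown"

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for run in self.ssr_runs:
            if not (0 <= run.start < run.end <= n):
                raise ValueError("ssr run outside sequence bounds")
        for s, e in self.tandem_units:
            if not (0 <= s < e <= n):
                raise ValueError("tandem unit outside sequence bounds")

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int) -> list[str]:
    return [BASES[i] for i in rng.integers(0, 4, size=n)]


def _random_flank(rng: np.random.Generator, n: int, min_run_bp: int = 15,
                  max_tries: int = 100) -> list[str]:
    """Random flank guaranteed free of SSR runs >= ``min_run_bp``."""
    if n == 0:
        return []
    for _ in range(max_tries):
        flank = _random_bases(rng, n)
        if not annotate_ssr_runs("".join(flank), min_run_bp=min_run_bp):
            return flank
    raise RuntimeError("could not draw a repeat-free flank")  # pragma: no cover


def _pin(rng: np.random.Generator, forbidden: str) -> str:
    choices = [b for b in BASES if b != forbidden]
    return choices[rng.integers(0, len(choices))]


def generate_ssr_fragment(spec: SSRFragmentSpec) -> AnnotatedSequence:
    """Construct an SSR-rich fragment from ``spec``.

    Deterministic for a fixed ``spec.seed``.  The returned annotation is the
    construction truth: one :class:`MotifRun` per block, with the exact
    positions of every planted variant.

    The two flank bases adjacent to the repeat region are chosen to break
    the repeat periodicity, so whole-copy run annotation of a variant-free
    fragment recovers the block intervals exactly (periodicity cannot leak
    into the flanks).
    """
    rng = np.random.default_rng(spec.seed)
    left = _random_flank(rng, spec.flank_lengths[0])
    right = _random_flank(rng, spec.flank_lengths[1])

    repeat: list[str] = []
    runs: list[MotifRun] = []
    offset = spec.flank_lengths[0]
    pos = offset
    for motif, count in spec.blocks:
        block = list(motif) * count
        runs.append(MotifRun(canonical_rotation(motif), pos, pos + len(block), count))
        repeat.extend(block)
        pos += len(block)

    first_motif, _ = spec.blocks[0]
    last_motif, _ = spec.blocks[-1]
    p1, pk = len(first_motif), len(last_motif)
    # pin the flank bases flanking the repeat region: two bases on each side
    # must differ from the periodic extension of the nearest block
    if len(left) >= 1:
        left[-1] = _pin(rng, first_motif[(p1 - 1) % p1])
    if len(left) >= 2:
        left[-2] = _pin(rng, first_motif[(p1 - 2) % p1])
    end_phase = len(repeat) % pk  # phase of the base just past the last block
    if len(right) >= 1:
        right[0] = _pin(rng, last_motif[end_phase])
    if len(right) >= 2:
        right[1] = _pin(rng, last_motif[(end_phase + 1) % pk])

    # plant single-base variants uniformly over the repeat region
    n_rep = len(repeat)
    variant_positions: list[int] = []
    if spec.variant_rate > 0 and n_rep:
        n_var = rng.binomial(n_rep, spec.variant_rate)
        variant_positions = sorted(rng.choice(n_rep, size=n_var, replace=False).tolist())
        for v in variant_positions:
            repeat[v] = _pin(rng, repeat[v])

    sequence = "".join(left) + "".join(repeat) + "".join(right)
    # attach recorded variants to their runs
    truth_runs: list[MotifRun] = []
    for run in runs:
        mism = tuple(offset + v for v in variant_positions
                     if run.start <= offset + v < run.end)
        truth_runs.append(MotifRun(run.motif, run.start, run.end, run.copy_count, mism))
    return AnnotatedSequence(sequence, ssr_runs=truth_runs,
                             source=f"ssr-spec:{spec.spec_hash()}")


def generate_tandem_array_fragment(spec: TandemArraySpec) -> AnnotatedSequence:
    """Construct a tandem gene array fragment from ``spec``.

    A master unit (random coding region + random spacer) is drawn once,
    then copied ``n_units`` times head-to-tail; each copy independently
    accumulates substitutions at ``per_unit_divergence``.  With divergence 0
    the array is exactly periodic.
    """
    rng = np.random.default_rng(spec.seed)
    left = _random_flank(rng, spec.flank_lengths[0])
    right = _random_flank(rng, spec.flank_lengths[1])
    master = _random_bases(rng, spec.unit_length)

    units: list[str] = []
    intervals: list[tuple[int, int]] = []
    pos = spec.flank_lengths[0]
    for _ in range(spec.n_units):
        copy = list(master)
        if spec.per_unit_divergence > 0:
            n_mut = rng.binomial(len(copy), spec.per_unit_divergence)
            for v in rng.choice(len(copy), size=n_mut, replace=False):
                copy[v] = _pin(rng, copy[v])
        units.append("".join(copy))
        intervals.append((pos, pos + spec.unit_length))
        pos += spec.unit_length

    sequence = "".join(left) + "".join(units) + "".join(right)
    return AnnotatedSequence(sequence, tandem_units=intervals,
                             source=f"tandem-spec:{spec.spec_hash()}")


def default_ssr_spec(seed: int = 0, total_length: int = 7333,
                     variant_rate: float = 0.01) -> SSRFragmentSpec:
    """An SSR fragment emulating a barley heterochromatic SSR stretch: the
    five trinucleotide motifs AAG, AGT, AAC, AAT and AGG interleaved in one
    uninterrupted repeat region of ~6.2 kb inside a ~7.3 kb fragment.

    The exact block order and copy numbers of the real fragment are not
    published as a table, so the default interleaves each motif twice with
    near-equal copy numbers summing to a 6201 bp repeat region.
    """
    motifs = ["AAG", "AGT", "AAC", "AAT", "AGG"]
    order = motifs + motifs  # each motif appears twice, no adjacent repeats
    n_blocks = len(order)
    # keep the reference proportions (6201 bp of repeats in 7333 bp) when
    # scaling to other fragment lengths
    repeat_bp = (min(total_length - 60, int(total_length * 6201 / 7333)) // 3) * 3
    if repeat_bp < 3 * n_blocks:
        raise InvalidSpecError("total_length too small for the default blocks")
    total_copies = repeat_bp // 3
    base = total_copies // n_blocks
    extra = total_copies - base * n_blocks
    counts = [base + (1 if i < extra else 0) for i in range(n_blocks)]
    flank_total = total_length - repeat_bp
    if flank_total < 0:
        raise InvalidSpecError("total_length too small for the default blocks")
    flanks = (flank_total // 2, flank_total - flank_total // 2)
    return SSRFragmentSpec(total_length=total_length,
                           blocks=tuple(zip(order, counts)),
                           variant_rate=variant_rate,
                           flank_lengths=flanks, seed=seed)


def default_tandem_spec(seed: int = 0) -> TandemArraySpec:
    """A 5S rRNA-like tandem array: 15 copies of a 120 bp coding region plus
    a 180 bp spacer, 4585 bp total with the default flanks."""
    return TandemArraySpec(unit_coding_length=120, nts_length=180, n_units=15,
                           per_unit_divergence=0.01, flank_lengths=(40, 45),
                           seed=seed)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def _scan_period(seq: str, p: int, min_run_bp: int,
                 max_interruptions: int | None) -> list[MotifRun]:
    """Left-to-right whole-copy run scan at a single motif period ``p``.

    A run starts at the first position of a complete motif copy, extends
    while bases match the periodic expectation, and tolerates isolated
    single-base interruptions (each must be followed by ``p`` matching
    bases).  The interruption budget is ``max_interruptions`` when given,
    else one per ten copies (minimum one).  The run is trimmed to whole
    copies of the motif.
    """
    n = len(seq)
    runs: list[MotifRun] = []
    i = 0
    while i <= n - 2 * p:
        motif = seq[i:i + p]
        if smallest_period(motif) < p:
            i += 1
            continue
        j = i + p
        mismatches: list[int] = []
        while j < n:
            if seq[j] == motif[(j - i) % p]:
                j += 1
                continue
            copies_so_far = (j - i) // p
            budget = (max_interruptions if max_interruptions is not None
                      else max(1, copies_so_far // 10))
            isolated = (j + p < n) and all(
                seq[j + 1 + t] == motif[(j + 1 + t - i) % p] for t in range(p)
            )
            if isolated and len(mismatches) < budget:
                mismatches.append(j)
                j += 1
            else:
                break
        end = i + p * ((j - i) // p)
        mism = tuple(m for m in mismatches if m < end)
        if end - i >= min_run_bp:
            runs.append(MotifRun(canonical_rotation(motif), i, end,
                                 (end - i) // p, mism))
            i = end
        else:
            i += 1
    return runs


def _resolve_overlaps(runs: list[MotifRun], min_run_bp: int,
                      sequence: str) -> list[MotifRun]:
    """Sort runs and make them non-overlapping.

    Same-motif overlapping or abutting runs are merged.  When runs of
    different motifs overlap (adjacent repeat blocks can share a phase-
    compatible junction, e.g. ...AAAG|AAG...), the earlier run keeps its
    territory and the later run is re-anchored at the earlier run's end --
    legitimate because any start phase inside a periodic region delimits
    the same whole-copy tiling.  A re-anchored remnant shorter than
    ``min_run_bp`` is dropped."""
    runs = sorted(runs, key=lambda r: (r.start, -(r.end - r.start)))
    out: list[MotifRun] = []
    for run in runs:
        if out and run.start < out[-1].end:
            prev = out[-1]
            if run.motif == prev.motif and len(run.motif) == len(prev.motif):
                p = len(prev.motif)
                merged_end = prev.start + p * ((max(prev.end, run.end)
                                                - prev.start) // p)
                mism = tuple(sorted(set(prev.mismatch_positions)
                                    | set(m for m in run.mismatch_positions
                                          if m < merged_end)))
                out[-1] = MotifRun(prev.motif, prev.start, merged_end,
                                   (merged_end - prev.start) // p, mism)
                continue
            p = len(run.motif)
            new_start = prev.end
            # re-trim to whole copies against the raw periodic extent: the
            # stretch may continue past run.end by a partial copy that a
            # shifted phase turns into a whole one
            raw_end = run.end
            n = len(sequence)
            while raw_end < n and sequence[raw_end] == sequence[raw_end - p]:
                raw_end += 1
            new_end = new_start + p * ((raw_end - new_start) // p)
            if new_end - new_start < min_run_bp:
                continue
            run = MotifRun(run.motif, new_start, new_end,
                           (new_end - new_start) // p,
                           tuple(m for m in run.mismatch_positions
                                 if new_start <= m < new_end))
        out.append(run)
    return out


def annotate_ssr_runs(sequence: str, min_run_bp: int = 15,
                      max_interruptions_per_run: int | None = None,
                      max_period: int = 6) -> list[MotifRun]:
    """Find maximal whole-copy SSR runs of period 1..``max_period``.

    Runs are reported under the canonical rotation of their motif and are
    non-overlapping.  An empty sequence yields an empty list.  Isolated
    single-base interruptions inside a run are tolerated (see
    :func:`_scan_period`) and reported in ``mismatch_positions``.
    """
    sequence = sequence.upper()
    if not sequence:
        return []
    runs: list[MotifRun] = []
    for p in range(1, max_period + 1):
        runs.extend(_scan_period(sequence, p, min_run_bp, max_interruptions_per_run))
    return _resolve_overlaps(runs, min_run_bp, sequence)


def continuous_ssr_regions(runs: list[MotifRun],
                           gap_merge_bp: int = 10,
                           sequence: str | None = None) -> list[tuple[int, int]]:
    """Merge runs (of any motif) separated by <= ``gap_merge_bp`` into
    "continuous SSR region" spans -- the uninterrupted-repeat-region view in
    which different motifs interleave.

    When ``sequence`` is given, each run's span is first extended over
    flanking *partial* motif copies (bases that continue the run's
    periodicity but do not complete a copy), so a region covers the full
    repetitive stretch rather than only whole copies."""
    if not runs:
        return []
    spans: list[tuple[int, int]] = []
    for run in sorted(runs, key=lambda r: r.start):
        s, e = run.start, run.end
        if sequence is not None:
            p = len(run.motif)
            n = len(sequence)
            while e < n and sequence[e] == sequence[e - p]:
                e += 1
            while s > 0 and sequence[s - 1] == sequence[s - 1 + p]:
                s -= 1
        spans.append((s, e))
    regions = [[spans[0][0], spans[0][1]]]
    for s, e in spans[1:]:
        if s - regions[-1][1] <= gap_merge_bp:
            regions[-1][1] = max(regions[-1][1], e)
        else:
            regions.append([s, e])
    return [(s, e) for s, e in regions]


# ---------------------------------------------------------------------------
# tandem unit counting
# ---------------------------------------------------------------------------


def _self_identity(arr: np.ndarray, p: int) -> float:
    return float(np.mean(arr[p:] == arr[:-p])) if p < len(arr) else 0.0


def count_tandem_units(sequence: str, seed_unit: str | None = None,
                       min_unit_bp: int = 50,
                       min_identity: float = 0.8) -> tuple[int, list[tuple[int, int]]]:
    """Count head-to-tail unit copies in a tandem array.

    When ``seed_unit`` is absent the unit period is self-detected: candidate
    periods ``p`` are scored by the identity of ``sequence[i]`` versus
    ``sequence[i + p]`` and the smallest period scoring at least
    ``min_identity`` wins.  The array region is then located with a short
    sliding identity window and tiled into equal unit intervals.

    Returns ``(n_units, unit_intervals)``; ``(0, [])`` when no periodicity
    above ``min_identity`` is detectable.  The interval phase is anchored at
    the detected array start; any phase yields the same unit count.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if n < 2 * min_unit_bp:
        return 0, []
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)

    if seed_unit is not None:
        p = len(seed_unit)
        if p < min_unit_bp or _self_identity(arr, p) < min_identity * 0.5:
            # seed unit may still be valid if the array is short relative to
            # the flanks; fall through to windowed confirmation below
            pass
    else:
        p = 0
        for cand in range(min_unit_bp, n // 2 + 1):
            if _self_identity(arr, cand) >= min_identity:
                p = cand
                break
        if p == 0:
            return 0, []

    m = (arr[p:] == arr[:-p]).astype(np.float64)
    w = max(10, min(40, p // 2))
    if len(m) < w:
        return 0, []
    window = np.convolve(m, np.ones(w) / w, mode="valid")
    hit = np.flatnonzero(window >= 0.75)
    if hit.size == 0:
        return 0, []
    i0, i1 = int(hit[0]), int(hit[-1])
    span = i1 + w - i0  # length of the matched comparison span ~ (n_units-1)*p
    n_units = int(round(span / p)) + 1
    if n_units < 2:
        return 0, []
    intervals = [(i0 + k * p, i0 + (k + 1) * p) for k in range(n_units)]
    if intervals[-1][1] > n:
        # clip a phase overshoot at the right edge by shifting the tiling
        shift = intervals[-1][1] - n
        intervals = [(s - shift, e - shift) for s, e in intervals]
        if intervals[0][0] < 0:
            return 0, []
    return n_units, intervals
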