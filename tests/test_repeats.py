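"""Generator / annotator tests for SSR runs and tandem arrays."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import exodel as x
from exodel.repeats import BASES, canonical_rotation, smallest_period

from conftest import random_seq


# ---------------------------------------------------------------------------
# independent oracle: naive whole-copy pure-run detection
# ---------------------------------------------------------------------------


def pure_run_candidates(s: str, min_run_bp: int, max_period: int = 6):
    """Brute force: for every start position and period, the longest stretch
    of complete, mismatch-free motif copies.  O(n * p * len) string
    comparison, no shared code with the annotator."""
    out = []
    n = len(s)
    for p in range(1, max_period + 1):
        for i in range(n - 2 * p + 1):
            motif = s[i:i + p]
            m = 1
            while s[i + m * p: i + (m + 1) * p] == motif:
                m += 1
            if m * p >= min_run_bp:
                out.append((i, i + m * p, canonical_rotation(motif)))
    return out


def assert_oracle_coverage(s: str, runs, min_run_bp: int = 15) -> None:
    """Every brute-force pure run long enough to stand on its own must be
    covered by an annotated run of the same canonical class (allowing the
    phase slack of up to one period at each end)."""
    by_class = {}
    for r in runs:
        by_class.setdefault(r.motif, []).append((r.start, r.end))
    for (a, b, motif) in pure_run_candidates(s, min_run_bp):
        p = len(motif)
        if smallest_period(motif) < p:
            continue
        covered = any(ra <= a + p and b - p <= rb
                      for ra, rb in by_class.get(motif, []))
        assert covered, f"pure run {motif} [{a},{b}) not covered by {runs}"


def assert_runs_sound(s: str, runs) -> None:
    """Soundness: every reported run's bases match its motif phase except at
    the listed mismatch positions, and no run can be extended by one whole
    copy into territory not claimed by a neighbouring run."""
    claimed = [(r.start, r.end) for r in runs]

    def free(a: int, b: int) -> bool:
        return all(b <= s0 or a >= e0 for s0, e0 in claimed
                   if (s0, e0) != (a, b))

    for r in runs:
        p = len(r.motif)
        assert (r.end - r.start) % p == 0
        assert r.copy_count == (r.end - r.start) // p
        phase_motif = s[r.start:r.start + p]
        assert canonical_rotation(phase_motif) == r.motif
        for i in range(r.start, r.end):
            expected = phase_motif[(i - r.start) % p]
            if i in r.mismatch_positions:
                assert s[i] != expected
            else:
                assert s[i] == expected
        # maximality at whole-copy granularity (outside neighbouring runs)
        left = s[r.start - p:r.start]
        if r.start >= p and free(r.start - p, r.start):
            assert left != phase_motif[-p:]
        right = s[r.end:r.end + p]
        tail_expected = "".join(phase_motif[(i - r.start) % p]
                                for i in range(r.end, r.end + p))
        if r.end + p <= len(s) and free(r.end, r.end + p):
            assert right != tail_expected


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


class TestGenerateSSR:
    def test_zero_noise_construction(self):
        spec = x.SSRFragmentSpec(total_length=170, blocks=(("AAG", 50),),
                                 variant_rate=0.0, flank_lengths=(10, 10), seed=1)
        frag = x.generate_ssr_fragment(spec)
        assert len(frag.sequence) == 170
        assert frag.sequence[10:160] == "AAG" * 50
        assert frag.ssr_runs == [x.MotifRun("AAG", 10, 160, 50)]

    def test_seed_determinism(self):
        spec = x.default_ssr_spec(seed=9, variant_rate=0.01)
        a = x.generate_ssr_fragment(spec)
        b = x.generate_ssr_fragment(spec)
        assert a.sequence == b.sequence
        assert a.ssr_runs == b.ssr_runs

    def test_default_emulates_long_uninterrupted_region(self, ssr_fragment):
        """Five trinucleotide motifs interleaved into ~6.2 kb of repeats
        inside a ~7.3 kb fragment."""
        assert len(ssr_fragment.sequence) == 7333
        motifs = {r.motif for r in ssr_fragment.ssr_runs}
        assert motifs == {"AAG", "AGT", "AAC", "AAT", "AGG"}
        repeat_bp = sum(r.length for r in ssr_fragment.ssr_runs)
        assert repeat_bp == 6201
        regions = x.continuous_ssr_regions(ssr_fragment.ssr_runs,
                                           sequence=ssr_fragment.sequence)
        assert len(regions) == 1
        assert regions[0][1] - regions[0][0] >= 6201

    def test_blocks_exceeding_length_rejected(self):
        with pytest.raises(x.InvalidSpecError):
            x.SSRFragmentSpec(total_length=100, blocks=(("AAG", 50),),
                              flank_lengths=(10, 10), seed=0)

    def test_variant_rate_bounds(self):
        with pytest.raises(x.InvalidSpecError):
            x.SSRFragmentSpec(total_length=160, blocks=(("AAG", 50),),
                              variant_rate=0.2, flank_lengths=(5, 5), seed=0)

    def test_variants_recorded_in_truth(self):
        spec = x.SSRFragmentSpec(total_length=1600, blocks=(("AAG", 500),),
                                 variant_rate=0.01, flank_lengths=(50, 50), seed=3)
        frag = x.generate_ssr_fragment(spec)
        run = frag.ssr_runs[0]
        assert len(run.mismatch_positions) > 0
        for v in run.mismatch_positions:
            assert frag.sequence[v] != "AAG"[(v - run.start) % 3]


class TestGenerateTandem:
    def test_paper_scale_array(self):
        frag = x.generate_tandem_array_fragment(x.default_tandem_spec(seed=1))
        assert len(frag.sequence) == 4585
        assert len(frag.tandem_units) == 15

    def test_single_unit(self):
        spec = x.TandemArraySpec(n_units=1, seed=2)
        frag = x.generate_tandem_array_fragment(spec)
        assert len(frag.tandem_units) == 1

    def test_exact_periodicity_at_zero_divergence(self):
        spec = x.TandemArraySpec(unit_coding_length=100, nts_length=100,
                                 n_units=3, per_unit_divergence=0.0,
                                 flank_lengths=(30, 30), seed=5)
        frag = x.generate_tandem_array_fragment(spec)
        unit = frag.sequence[30:230]
        assert frag.sequence[30:630] == unit * 3


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


class TestAnnotateSSR:
    def test_empty_sequence(self):
        assert x.annotate_ssr_runs("") == []

    def test_random_sequence_has_no_runs(self, rng):
        s = random_seq(rng, 1000)
        runs = x.annotate_ssr_runs(s, min_run_bp=15)
        assert_runs_sound(s, runs)  # usually empty; any hit must be genuine

    def test_constructed_two_run_example(self):
        """(AAG)x50 + TTCTT + (AGT)x30: two whole-copy runs of 150 and 90 bp
        merging into one 245 bp continuous region."""
        s = "AAG" * 50 + "TTCTT" + "AGT" * 30
        runs = x.annotate_ssr_runs(s, min_run_bp=15)
        assert [(r.motif, r.length, r.copy_count) for r in runs] == [
            ("AAG", 150, 50), ("AGT", 90, 30)]
        regions = x.continuous_ssr_regions(runs, gap_merge_bp=10, sequence=s)
        assert regions == [(0, 245)]
        assert regions[0][1] - regions[0][0] == 245
        assert_oracle_coverage(s, runs)

    def test_interruption_tolerated_and_reported(self):
        # one substitution (A->T at a copy start) inside 41 copies
        s = "CC" + "AAG" * 20 + "TAG" + "AAG" * 20 + "CC"
        runs = x.annotate_ssr_runs(s, min_run_bp=15)
        assert len(runs) == 1
        run = runs[0]
        assert run.motif == "AAG"
        assert len(run.mismatch_positions) == 1
        assert_runs_sound(s, runs)

    def test_canonical_rotation_stability(self):
        """A pure repeat and its 1-base rotation annotate to the same
        canonical motif class."""
        s1 = "GAA" * 30
        s2 = s1[1:] + s1[:1]
        m1 = x.annotate_ssr_runs(s1)[0].motif
        m2 = x.annotate_ssr_runs(s2)[0].motif
        assert m1 == m2 == "AAG"

    @pytest.mark.parametrize("seed", range(5))
    def test_roundtrip_exact_at_zero_variant_rate(self, seed):
        """Annotation recovers the generating blocks exactly when no
        variants were planted."""
        spec = x.SSRFragmentSpec(
            total_length=2000,
            blocks=(("AAG", 150), ("AGT", 120), ("AAT", 130), ("AGG", 100)),
            variant_rate=0.0, flank_lengths=(250, 250), seed=seed)
        frag = x.generate_ssr_fragment(spec)
        runs = x.annotate_ssr_runs(frag.sequence)
        assert runs == frag.ssr_runs

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_roundtrip_property_random_specs(self, seed):
        rng = np.random.default_rng(seed)
        motifs = ["AAG", "AGT", "AAC", "AAT", "AGG", "AC", "AAAG"]
        rng.shuffle(motifs)
        blocks = tuple((m, int(rng.integers(10, 60))) for m in motifs[:3])
        rep = sum(len(m) * c for m, c in blocks)
        spec = x.SSRFragmentSpec(total_length=rep + 200, blocks=blocks,
                                 variant_rate=0.0, flank_lengths=(100, 100),
                                 seed=seed)
        frag = x.generate_ssr_fragment(spec)
        runs = x.annotate_ssr_runs(frag.sequence)
        assert runs == frag.ssr_runs
        assert_runs_sound(frag.sequence, runs)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_agrees_with_brute_force_on_random_mosaics(self, seed):
        """Random sequences with occasional planted repeats: every pure run
        the brute-force scan finds is covered, and every reported run is
        sound and maximal."""
        rng = np.random.default_rng(seed)
        parts = []
        for _ in range(6):
            parts.append(random_seq(rng, int(rng.integers(20, 120))))
            motif = random_seq(rng, int(rng.integers(1, 7)))
            parts.append(motif * int(rng.integers(2, 30)))
        s = "".join(parts)[:2000]
        runs = x.annotate_ssr_runs(s, min_run_bp=15)
        assert_runs_sound(s, runs)
        assert_oracle_coverage(s, runs)
        # non-overlap invariant
        for a, b in zip(runs, runs[1:]):
            assert a.end <= b.start


class TestCountTandemUnits:
    def test_exact_triplication(self, rng):
        unit = random_seq(rng, 200)
        n, intervals = x.count_tandem_units(unit * 3)
        assert n == 3
        assert intervals == [(0, 200), (200, 400), (400, 600)]

    def test_generator_truth_is_recovered(self):
        spec = x.TandemArraySpec(unit_coding_length=120, nts_length=180,
                                 n_units=7, per_unit_divergence=0.02,
                                 flank_lengths=(60, 60), seed=11)
        frag = x.generate_tandem_array_fragment(spec)
        n, intervals = x.count_tandem_units(frag.sequence)
        assert n == 7
        # intervals tile without overlap
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert e1 == s2

    def test_no_periodicity_returns_zero(self, rng):
        n, intervals = x.count_tandem_units(random_seq(rng, 1500))
        assert (n, intervals) == (0, [])

    def test_phase_invariance(self, rng):
        """Rotating the array by part of a unit does not change the count."""
        unit = random_seq(rng, 150)
        base = unit * 6
        for shift in (0, 37, 74, 149):
            n, _ = x.count_tandem_units(base[shift:] + base[:shift])
            assert n == 6

    def test_seed_unit_fixes_period(self, rng):
        unit = random_seq(rng, 300)
        s = random_seq(rng, 100) + unit * 5 + random_seq(rng, 100)
        n, _ = x.count_tandem_units(s, seed_unit=unit)
        assert n == 5


class TestMotifHelpers:
    @pytest.mark.parametrize("motif,expect", [
        ("AAG", "AAG"), ("AGA", "AAG"), ("GAA", "AAG"),
        ("T", "T"), ("TA", "AT"), ("CAGT", "AGTC")])
    def test_canonical_rotation(self, motif, expect):
        assert canonical_rotation(motif) == expect

    @pytest.mark.parametrize("motif,period", [
        ("AAAA", 1), ("ATAT", 2), ("ACG", 3), ("AAGAAG", 3), ("AAGT", 4)])
    def test_smallest_period(self, motif, period):
        assert smallest_period(motif) == period

    def test_reverse_complement(self):
        assert x.reverse_complement("AAGCT") == "AGCTT"
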