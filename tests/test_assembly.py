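"""Tests for the ordered overlap-layout-consensus assembler."""

import numpy as np
import pytest

import exodel as x
from exodel.assembly import OrderedReadSet

from conftest import random_seq


def reads_from_truth(truth: str, deletions, read_len=500):
    """Error-free reads at the given deletion depths, fragment coords."""
    return [truth[d:d + read_len] for d in deletions]


def make_read_set(truth, deletions, read_len=500, band=30, approx=None,
                  exact=None):
    reads = reads_from_truth(truth, deletions, read_len)
    offsets = [deletions[i + 1] - deletions[i] for i in range(len(deletions) - 1)]
    return OrderedReadSet(
        reads=reads,
        approx_offsets=approx if approx is not None else [float(o) for o in offsets],
        exact_offsets=exact, band_bp=band,
        expected_overlap_bp=read_len - float(np.mean(offsets)))


class TestFindOffset:
    def test_identical_reads_offset_zero(self, rng):
        r = random_seq(rng, 400)
        hyps = x.find_offset(r, r, approx_offset=0, band_bp=50, min_overlap=100)
        best = hyps[0]
        assert best.offset_bp == 0
        assert best.mismatches == 0
        assert best.score == pytest.approx(1.0)

    def test_unique_offset_in_unique_sequence(self, rng):
        truth = random_seq(rng, 1200)
        left, right = truth[:500], truth[400:900]
        hyps = x.find_offset(left, right, 390, band_bp=50, min_overlap=50)
        assert hyps[0].offset_bp == 400
        assert hyps[0].score == pytest.approx(1.0)
        assert hyps[1].score < 0.5  # runner-up is garbage in unique sequence

    def test_perfect_repeat_ties_mod_period(self):
        """Pure (AAG)n truth: exhaustive search ties exactly at offsets
        congruent to the true offset modulo 3."""
        truth = "AAG" * 400
        left, right = truth[:500], truth[400:900]
        hyps = x.find_offset(left, right, 400, band_bp=60, min_overlap=100,
                             exhaustive=True)
        top = [h for h in hyps if h.score == pytest.approx(1.0)]
        offsets = sorted(h.offset_bp for h in top)
        assert offsets == [o for o in range(0, 401) if o % 3 == 400 % 3]

    def test_variants_break_the_tie_with_anchor_support(self):
        """1% single-base variants in the repeat make the true offset the
        unique best, supported by shared anchors."""
        frag = x.generate_ssr_fragment(x.SSRFragmentSpec(
            total_length=1500, blocks=(("AAG", 500),), variant_rate=0.01,
            flank_lengths=(0, 0), seed=5))
        truth = frag.sequence
        left, right = truth[:500], truth[400:900]
        hyps = x.find_offset(left, right, 400, band_bp=60, min_overlap=100)
        assert hyps[0].offset_bp == 400
        assert hyps[0].anchor_support >= 1
        assert hyps[1].score < hyps[0].score

    def test_no_overlap_raises(self, rng):
        with pytest.raises(x.NoOverlapError):
            x.find_offset(random_seq(rng, 200), random_seq(rng, 200),
                          approx_offset=300, band_bp=10, min_overlap=100)


class TestResolveAmbiguity:
    def _tie(self, offsets, anchors=None):
        anchors = anchors or [0] * len(offsets)
        return [x.OffsetHypothesis(o, 1.0, 100, 0, a, True)
                for o, a in zip(offsets, anchors)]

    def test_single_hypothesis_is_unique(self):
        join = x.resolve_ambiguity(self._tie([400]))
        assert join.status == "unique"
        assert join.chosen_offset == 400

    def test_tie_with_exact_size_resolved(self):
        join = x.resolve_ambiguity(self._tie([397, 400, 403]), exact_offset=400)
        assert join.status == "ambiguous_resolved_by_size"
        assert join.chosen_offset == 400
        assert set(join.tied_offsets) == {397, 400, 403}

    def test_tie_without_information_stays_unresolved(self):
        join = x.resolve_ambiguity(self._tie([397, 400, 403]))
        assert join.status == "ambiguous_unresolved"
        assert len(join.tied_offsets) == 3

    def test_tie_resolved_by_strict_anchor_majority(self):
        join = x.resolve_ambiguity(self._tie([397, 400, 403], [0, 2, 0]))
        assert join.status == "ambiguous_resolved_by_anchors"
        assert join.chosen_offset == 400

    def test_tied_anchors_do_not_resolve(self):
        join = x.resolve_ambiguity(self._tie([397, 400, 403], [1, 1, 0]))
        assert join.status == "ambiguous_unresolved"

    def test_incompatible_exact_size_raises(self):
        with pytest.raises(x.InconsistentSizeError):
            x.resolve_ambiguity(self._tie([397, 400, 403]), exact_offset=250)


class TestOrientReads:
    def test_all_forward_is_identity(self, rng):
        truth = random_seq(rng, 1400)
        reads = reads_from_truth(truth, [0, 400, 800])
        rs = x.orient_reads(reads, [400.0, 400.0],
                            orientations=["forward"] * 3, band_bp=30)
        assert rs.reads == reads

    def test_known_reverse_reads_are_flipped_back(self, rng):
        truth = random_seq(rng, 1400)
        reads = reads_from_truth(truth, [0, 400, 800])
        emitted = [reads[0], x.reverse_complement(reads[1]), reads[2]]
        rs = x.orient_reads(emitted, [400.0, 400.0],
                            orientations=["forward", "reverse", "forward"],
                            band_bp=30)
        assert rs.reads == reads

    def test_unknown_orientations_recovered_from_overlap(self, rng):
        """Two reads, orientations unknown, one true overlap: the 4-way
        check recovers fragment coordinates (up to global strand choice)."""
        truth = random_seq(rng, 1000)
        a, b = truth[:500], truth[400:900]
        rs = x.orient_reads([a, x.reverse_complement(b)], [400.0],
                            orientations=[None, None], band_bp=30)
        assert rs.reads == [a, b]
        assert rs.orientation_flags == ["orientation_inferred"] * 2

    def test_simulator_truth_orientations_match(self, small_construct):
        pool = [x.DeletionMolecule(d, 0, small_construct)
                for d in range(0, 1300, 100)]
        ladder = x.simulate_gel_size_selection(pool, 400, 0.0, seed=9)
        reads = [x.simulate_sanger_read(e, i, read_length=500, error_rate=0.0,
                                        seed=i)
                 for i, e in enumerate(ladder.selected)]
        rs = x.orient_reads(reads, ladder.estimated_offsets, band_bp=10)
        truth = small_construct.sequence
        for read, entry in zip(rs.reads, ladder.selected):
            d = entry.molecule.true_deletion_bp
            assert read == truth[d:d + 500]

    def test_unplaceable_read_raises(self, rng):
        with pytest.raises(x.UnplaceableReadError):
            x.orient_reads([random_seq(rng, 500), random_seq(rng, 500)],
                           [400.0], orientations=["forward", None],
                           band_bp=30, min_overlap=50)


class TestAssemble:
    def test_error_free_roundtrip_small(self):
        frag = x.generate_ssr_fragment(x.SSRFragmentSpec(
            total_length=2100, blocks=(("AAG", 300), ("AAT", 300)),
            variant_rate=0.01, flank_lengths=(150, 150), seed=3))
        truth = frag.sequence
        deletions = list(range(0, 1601, 400))
        rs = make_read_set(truth, deletions, band=0)
        result = x.assemble(rs)
        assert result.consensus == truth
        assert all(j.status == "unique" for j in result.joins)
        assert all(d >= 1 for d in result.per_position_depth[0])

    def test_two_reads_without_overlap_give_two_contigs(self, rng):
        truth = random_seq(rng, 2000)
        rs = OrderedReadSet(reads=[truth[:500], truth[1500:2000]],
                            approx_offsets=[1500.0], band_bp=50)
        result = x.assemble(rs)
        assert len(result.contigs) == 2
        assert any("contig break" in f for f in result.flags)

    def test_consensus_length_conservation(self, rng):
        truth = random_seq(rng, 1700)
        deletions = [0, 350, 700, 1050]
        rs = make_read_set(truth, deletions, read_len=500, band=20)
        result = x.assemble(rs)
        assert len(result.contigs) == 1
        assert len(result.contigs[0]) == 500 + sum(
            j.chosen_offset for j in result.joins)

    def test_duplicate_clone_merges_into_depth(self, rng):
        """A second clone at the same deletion adds coverage, not length."""
        truth = random_seq(rng, 1200)
        rs = make_read_set(truth, [0, 400, 400, 800], read_len=500, band=20)
        result = x.assemble(rs, min_overlap=100)
        assert result.consensus == truth
        depth = result.per_position_depth[0]
        assert depth[450] >= 2

    def test_majority_vote_suppresses_read_errors(self, rng):
        """With depth >= 2 everywhere, isolated single-read errors are
        outvoted wherever a correct read also covers the position."""
        truth = random_seq(rng, 1300)
        deletions = [0, 200, 400, 600, 800]
        reads = [list(truth[d:d + 500]) for d in deletions]
        # plant one error per read, all at distinct consensus positions
        for i, r in enumerate(reads):
            r[250] = {"A": "C", "C": "G", "G": "T", "T": "A"}[r[250]]
        rs = OrderedReadSet(reads=["".join(r) for r in reads],
                            approx_offsets=[200.0] * 4, band_bp=10)
        result = x.assemble(rs, tie_tolerance=0.05)
        assert len(result.contigs) == 1
        errors = sum(a != b for a, b in zip(result.contigs[0], truth))
        assert errors <= 1  # only the depth-1 first-read prefix can survive

    def test_monotone_degradation_with_error_rate(self, small_construct):
        """Assembly identity is non-increasing in the read error rate at a
        fixed seed set (errors are coupled across rates)."""
        pool = [x.DeletionMolecule(d, 0, small_construct)
                for d in range(0, 1700, 100)]
        ladder = x.simulate_gel_size_selection(pool, 400, 0.0, seed=5)
        truth = small_construct.sequence
        identities = []
        for rate in (0.0, 0.002, 0.01, 0.03):
            reads = [x.simulate_sanger_read(e, i, read_length=500,
                                            error_rate=rate, seed=1000 + i)
                     for i, e in enumerate(ladder.selected)]
            rs = x.orient_reads(reads, ladder.estimated_offsets, band_bp=5)
            result = x.assemble(rs, tie_tolerance=0.0)
            report = x.evaluate_against_truth(result, truth)
            identities.append(report.identity)
        assert identities[0] == 1.0
        assert all(a >= b for a, b in zip(identities, identities[1:]))


class TestPerfectRepeatAmbiguity:
    TRUTH = "AAG" * 800  # 2400 bp pure repeat, zero variants

    def test_assembler_flags_instead_of_guessing(self):
        deletions = list(range(0, 1601, 400))
        rs = make_read_set(self.TRUTH, deletions, band=30)
        result = x.assemble(rs)
        assert result.consensus is None
        assert len(result.contigs) == len(deletions)
        assert all(j.status == "ambiguous_unresolved" for j in result.joins)
        for j in result.joins:
            assert len(j.tied_offsets) >= 2
            assert all(o % 3 == 400 % 3 for o in j.tied_offsets)

    def test_exact_sizes_recover_truth(self):
        deletions = list(range(0, 1601, 400))
        rs = make_read_set(self.TRUTH, deletions, band=30,
                           exact=[400] * 4)
        result = x.assemble(rs)
        assert result.consensus == self.TRUTH[:500 + 1600]
        assert all(j.status == "ambiguous_resolved_by_size"
                   for j in result.joins)

    def test_banded_equals_exhaustive_when_truth_in_band(self):
        truth = x.generate_ssr_fragment(x.SSRFragmentSpec(
            total_length=1500, blocks=(("AAG", 500),), variant_rate=0.01,
            flank_lengths=(0, 0), seed=8)).sequence
        left, right = truth[:500], truth[400:900]
        banded = x.find_offset(left, right, 400, band_bp=60, min_overlap=100)
        exhaustive = x.find_offset(left, right, 400, band_bp=60,
                                   min_overlap=100, exhaustive=True)
        assert banded[0].offset_bp == exhaustive[0].offset_bp == 400
        assert banded[0].score == exhaustive[0].score


class TestEvaluate:
    def test_perfect_assembly_scores_identity_one(self, rng):
        truth = random_seq(rng, 800)
        result = x.AssemblyResult([truth], [], [np.ones(800, int)], [], [[0]])
        report = x.evaluate_against_truth(result, truth)
        assert report.identity == 1.0
        assert report.exact

    def test_substitutions_counted_positionally(self, rng):
        truth = random_seq(rng, 7333)
        bad = list(truth)
        for i in (10, 700, 7000):
            bad[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bad[i]]
        result = x.AssemblyResult(["".join(bad)], [], [np.ones(7333, int)],
                                  [], [[0]])
        report = x.evaluate_against_truth(result, truth)
        assert report.matches == 7330
        assert report.identity == pytest.approx(7330 / 7333)

    def test_length_mismatch_reported_not_raised(self, rng):
        truth = random_seq(rng, 500)
        result = x.AssemblyResult([truth[:400]], [], [np.ones(400, int)],
                                  [], [[0]])
        report = x.evaluate_against_truth(result, truth)
        assert report.length_mismatch == -100
        assert any("length mismatch" in n for n in report.notes)
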