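# Methods

This note documents the models behind `exodel`: what each stage of the
simulated nested-deletion experiment assumes, which parameters matter and
why their defaults are what they are, and what the synthetic data can and
cannot say about real campaigns.

## Coordinate conventions

All coordinates are 0-based, half-open.  Construct coordinates are
oriented so that digestion proceeds left to right: position 0 is the
unprotected restriction cut, the protected end is the right end of the
string, a clone with deletion depth *d* retains `construct[d:]`, and its
read covers `construct[d : d + read_len]`.  This may be the reverse
complement of the biological top strand; in silico the choice is
immaterial, and it makes reads, offsets and assembly all run in one
direction.  Human-readable reports use 1-based inclusive coordinates only
where explicitly labelled.

## Ground-truth generators

**SSR fragments** are built from an ordered list of motif blocks laid down
contiguously (an uninterrupted repeat region) between two random,
repeat-free flanks.  The default recipe interleaves the five
trinucleotide motifs AAG, AGT, AAC, AAT and AGG (each twice, near-equal
copy numbers) into a 6201 bp repeat region inside a 7333 bp fragment,
mirroring a barley heterochromatic SSR stretch; other lengths scale the
repeat region proportionally.  Single-base variants are planted uniformly
over the repeat region at `variant_rate` (default 0.01 per bp, bounded at
0.05) and recorded in the truth annotation — these are the anchors the
assembler later relies on.  The two flank bases adjacent to the repeat
region are chosen to break the repeat periodicity, so whole-copy run
annotation of a variant-free fragment recovers the generating blocks
*exactly* rather than up to a phase shift.

**Tandem arrays** copy a random master unit (coding region + spacer,
defaults 120 + 180 bp) head-to-tail `n_units` times (default 15,
total 4585 bp with the default flanks); each copy independently
accumulates substitutions at `per_unit_divergence` (default 0.01).  The
generator uses a fixed spacer length per array; real arrays can vary
spacer length between copies (see Limitations).

## Repeat annotation

An SSR run is a maximal stretch of *complete* motif copies (period 1–6)
at a fixed phase, tolerating isolated single-base interruptions — an
interruption must be followed by a full matching copy, and the budget is
one per ten copies (minimum one) unless overridden.  Runs are trimmed to
whole copies and reported under the canonical (lexicographically least)
rotation of their motif, so AAG/AGA/GAA are one class;
reverse-complement motifs are a separate class because annotation is
single-stranded.  Overlapping runs of different motifs (adjacent blocks
can share a phase-compatible junction, e.g. `…AAAG|AAG…`) are resolved by
letting the earlier run keep its territory and re-anchoring the later
run at its end — legitimate because any start phase inside a periodic
region delimits the same whole-copy tiling.  "Continuous SSR regions"
merge runs of any motif separated by ≤ `gap_merge_bp` (default 10 bp),
after extending each run over flanking partial copies; this is the
"uninterrupted region" view in which different motifs interleave.

Tandem-unit counting is deliberately simple and oracle-checkable: the
unit period is the smallest *p* ≥ `min_unit_bp` whose global self-identity
`mean(s[i] == s[i+p])` reaches `min_identity` (default 0.8); the array
region is then located with a short sliding identity window (≥ 75% matches
over min(40, p/2) bp) and tiled into equal units.  The count is derived
from the matched span length, so it is invariant to the phase chosen for
the unit boundaries.

## The wet-lab model

**Construct.**  The fragment sits between a protective cut (modelled 8 bp
past the insert) and a blunt cut (87 bp past the other end), matching the
reference design.  The 4-base 3′ overhang is modelled as absolutely
protective — the literature says overhangs *longer* than 4 bases block
the enzyme and the reference experiment protected with a 4-base overhang;
whether 4 bases are fully protective cannot be settled from the text, so
the simulator takes the experiment's success at face value.  S1 trimming
of single-stranded tails is folded into the deletion depth (reads only
ever see double-stranded endpoints), and the vector is treated as fully
degraded during digestion: vector sequence never appears in reads.

**Digestion kinetics.**  Deletion depth after time *t* is Gamma
distributed with mean `rate × t` (default 450 bp/min at 37 °C) and shape
*k* = 1.2.  The shape is the one genuinely free parameter: the mean is
pinned by the published rate, while the qualitative spread ("a few bases
to more than 2000 bp per aliquot") constrains the tails.  At *k* = 1.2
the 2-minute depth distribution has its 5th percentile near 70 bp and its
95th near 2.5 kb, satisfying both ends; *k* = 2 would put the 5th
percentile at ~160 bp, too narrow at the low end.  Molecules digested
past the protected site are degraded and silently lost from the pool —
the source of a small downward truncation bias in mean depth on short
constructs (negligible at paper scale).  Digestion is strictly
unidirectional by construction.

**Schedule planning.**  `plan_digestion_schedule` picks the smallest
number of timed aliquots (2 min start, 90 s increments by default) whose
central-98% depth ranges, with the first range anchored at zero, jointly
span the fragment, and reports the tiling bound
`min_clones = ceil((L − read_len)/spacing) + 1`.  A design whose reads
cannot overlap consecutive rungs by at least `min_overlap` (default
100 bp) is rejected as infeasible rather than silently planned.

**Gel selection.**  Clone sizes are estimated with Gaussian noise
(`size_noise_sd_bp`).  The undeleted original clone is known a priori (it
is the first gel lane) and anchors the ladder; selection then greedily
picks the clone whose estimated size is closest to `previous − 400` among
candidates within one spacing window, stopping once the estimate drops to
the read length.  A window with no candidate triggers a gap warning
naming the uncovered interval.  The noise default is 25 bp: an offset
estimate is the difference of two noisy sizes (sd √2·σ), and with σ = 25
the probability that a true deletion step exceeds
`read_len − min_overlap` — an undetectable coverage gap that tandem
periodicity can silently paper over — stays below ~1% per campaign,
consistent with the reliable outcomes the strategy reports.  At σ = 50
such masked gaps corrupt a third of simulated campaigns, which is why the
larger value was rejected as a default (it remains available in config).

**Orientation.**  Each selected clone is inserted in a random
orientation.  The simulated assay digests the clone (asymmetric vector
arms, 10.3 kb / 2.2 kb by default) at an IUPAC recognition pattern
(default `GGCCNNNNNGGCC`) and compares the observed band sizes with the
patterns predicted for either orientation; identical predictions (no site
in the insert, or symmetric placement) raise an undecidable error and the
pipeline falls back to scoring both orientations of the read against its
neighbour.  The campaign pipeline plants the site near the protected end
of the fragment, where every deletion clone retains it.

**Reads.**  One read per clone, starting exactly at the deleted end,
length drawn from a normal(700, 60) clipped to [550, 900] bp (Sanger
chemistry routinely reads 700–900 bp; "over 500 bp" is a floor, and a
read shorter than spacing + 100 bp cannot bridge its rung), substitution
errors i.i.d. at `error_rate` (default 0.001, post-trim high-quality
calls).  Error draws are coupled across rates at a fixed seed (a higher
rate yields a superset of error positions), which makes
identity-vs-error-rate curves monotone by construction and testable.

## Ordered assembly

Candidate offsets between consecutive oriented reads are scored by the
per-base overlap score `(matches − 2·mismatches)/overlap_len` over the
implied overlap (minimum 100 bp).  A per-base score — rather than a raw
match count — is essential: hypotheses with different overlap lengths
must be comparable, and inside a perfect repeat every offset congruent to
the truth modulo the period then ties at exactly 1.0, which is the
mathematically honest answer.  The banded search covers ±3·√2·σ around
the gel-estimated offset (±107 bp at default noise); an exhaustive mode
scores every feasible offset.

Resolution proceeds in strict order of evidence quality:

1. a unique top score → `unique`;
2. scores tied within `tie_tolerance` (campaign default 0.02, sized to
   read-error jitter) and an externally measured exact offset → the
   measured offset wins, validated only by a score floor
   (`ambiguous_resolved_by_size`);
3. a strict majority of anchor support among the tied hypotheses →
   `ambiguous_resolved_by_anchors`.  An anchor is an agreed base in the
   overlap that differs from the bases one period earlier *and* later in
   its annotated run — a shared single-base variant.  Anchors act only
   inside score ties, never against a strictly better score;
4. otherwise `ambiguous_unresolved`: the join reports every tied offset
   and the consensus is split into contigs.  Ambiguity is a first-class
   result, never silently resolved.

A best in-band score below `min_join_score` (default 0.5) is reported as
a contig break: no offset explains the data, which in practice means the
gel let a deletion step exceed the read length.  A complete single-contig
assembly is additionally checked against the gel-estimated size of the
full-length clone; a shortfall of a repeat-unit length flags a possible
collapsed join.  The consensus is a positional majority vote (ties go to
the earliest covering read), and duplicate clones at the same offset
simply deepen the vote.

Evaluation against a known truth is strictly positional (identity =
matches / truth length, consensus anchored at position 0); length
mismatches are reported, not raised.

## Problem sizes and determinism

Simulated campaigns use 9000 digestion molecules (3000 per aliquot),
enough that the deep tail of the third aliquot covers the far end of a
7.5 kb fragment with ~50 bp granularity; a full campaign runs in well
under a second.  The acceptance experiments use 10 campaigns for the
clone count and 10,000 molecules for the kinetics mean.  Every stage
draws from an independent substream (`numpy` `SeedSequence.spawn`) of one
top-level seed, so a (config, seed) pair reproduces byte-identical output
files; run manifests contain no timestamps.

## What the synthetic data does not show

* Variants are planted uniformly; real SSR stretches have clustered,
  motif-biased variation.  Passing the round-trip test shows the ordered
  strategy works *given* roughly one anchor per overlap, not that any
  particular genomic region supplies them.  With the default 1% rate and
  ~100–300 bp overlaps, a few percent of joins in a noisy-gel campaign
  genuinely lack anchors and are honestly reported ambiguous; exact sizes
  resolve them.
* Tandem arrays use a fixed spacer length; unit counting by global
  self-identity would need per-unit alignment for strongly
  length-variable spacers.
* No indel errors in reads (substitution-only Sanger model), no
  chromatogram quality values, no cloning failures or chimeras, no
  sequence-dependent digestion pauses.
* The orientation assay models band *sizes* only, with exact comparison;
  real gels compare patterns with finite resolution.
* Accession-based reproduction (`fetch_accession`) requires network
  access on first use; offline it fails loudly rather than substituting
  synthetic data.
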