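# exodel

In-silico nested-deletion sequencing of repetitive DNA: a simulator of the
exonuclease III serial-deletion strategy, and the ordered
overlap-layout-consensus assembler it enables.

## The problem

Long stretches of tandemly repeated DNA — microsatellite (SSR) blocks of
heterochromatin, arrays of ribosomal genes — defeat both shotgun assembly
(near-identical reads collapse into a single contig) and primer walking
(no unique annealing sites).  One classical escape is to impose *external
order* on the reads: clone the fragment with one end protected (a 4-base
3′ overhang blocks exonuclease III) and one end exposed, digest for
staggered times at ~450 bp/min so each time point yields progressively
deeper unidirectional deletions, size-select clones ~400 bp apart on a
gel, and take a single vector-primer Sanger read from each deleted end.
The reads then *must* follow one another at known approximate offsets, so
assembly reduces to confirming ~100–300 bp overlaps between consecutive
reads instead of searching a repeat-saturated overlap graph.

`exodel` models every informational step of that experiment — construct
ends, digestion kinetics and dispersion, gel size selection with noise,
orientation calling by restriction banding, Sanger reads with substitution
errors — and implements the ordered assembler with the two mechanisms that
make repeats tractable:

* **anchors** — single-base departures from the repeat periodicity shared
  by two overlapping reads, which break the offset degeneracy of a
  near-perfect repeat;
* **exact deletion sizes** — a fragment-analyzer measurement that resolves
  the one case anchors cannot: a mathematically perfect repeat.

The package is a library first (`import exodel`), with narrative scripts
under `examples/` and a thin `exodel` command-line wrapper.

## The core computation

For consecutive reads \(r_i, r_{i+1}\) (oriented, ordered by deletion
depth) with gel-estimated offset \(\hat{o}_i\), the assembler scores every
integer offset \(o \in [\hat o_i - b,\ \hat o_i + b]\) by the per-base
overlap score

```
S(o) = (matches − 2·mismatches) / overlap_len,   overlap_len ≥ 100
```

Inside a pure repeat of period *p*, all offsets with *o ≡ o\* (mod p)* tie
at S = 1.  Ties (within a configurable tolerance) are resolved by, in
order: an externally measured exact offset; a strict majority of anchor
support; otherwise the join is reported `ambiguous_unresolved` and the
consensus is split — the assembler never guesses.  The consensus is a
positional majority vote over the placed reads.

## Worked example

`python examples/03_end_to_end_ssr_campaign.py` simulates the full
campaign on a 7.5 kb fragment whose middle ~6.3 kb is an uninterrupted
mosaic of AAG/AGT/AAC/AAT/AGG trinucleotide repeats with 1% single-base
variants, under clean conditions (noise-free gel, error-free 500 bp
reads):

```
truth fragment: 7500 bp (construct with vector pads: 7595 bp)
ladder: 19 clones, estimated sizes 7595 -> 466 bp
orientations called by restriction banding: 19/19
assembly: 1 contig(s), 18 joins, statuses ['unique']
identity vs truth: 100.000% (7595/7595)
annotated continuous SSR region in the consensus: 6342 bp
```

Nineteen ordered clones at ~400 bp spacing reconstruct the fragment
base-perfectly; every join is uniquely resolved because each ~100 bp
overlap carries at least one anchor variant.
`examples/04_perfect_repeat_ambiguity.py` shows the opposite limit — on a
variant-free (AAG)ₙ repeat all joins tie modulo 3 and the assembler
refuses to choose until exact deletion sizes are supplied, after which the
reconstruction is again exact.  `examples/05_tandem_array_campaign.py`
sequences a 4585 bp tandem array and re-detects its 15 units from the
consensus alone.

The same campaigns run from the shell:

```
exodel run --preset ssr-campaign --seed 11 --out out/ssr
exodel annotate out/ssr/consensus.fasta
```

Exit status distinguishes a clean assembly (0), an assembly with
unresolved ambiguities (3), and contig breaks (4).

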