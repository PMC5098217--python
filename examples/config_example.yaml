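# Full campaign configuration for `exodel run --config <file>`.
# Every key is optional; omitted keys take the defaults shown here.
# Exactly one truth source is active, chosen by truth_kind.

seed: 11                       # one top-level seed; every stage derives a substream
output_dir: exodel-out/custom  # all artifacts (FASTA/FASTQ/TSV/JSON) land here

truth_kind: ssr                # ssr | tandem | fasta | genbank | accession
truth_path: null               # FASTA/GenBank path when truth_kind is fasta/genbank
accession: null                # e.g. KX279876 when truth_kind is accession

ssr:                           # synthetic SSR fragment (truth_kind: ssr)
  total_length: 7333           # bp; repeat region scales proportionally
  variant_rate: 0.01           # per-base anchor variants inside the repeat region
  blocks: null                 # [[AAG, 207], [AGT, 207], ...] or null -> default mix
  flank_lengths: null          # [left, right] bp or null -> split the remainder

tandem:                        # synthetic tandem array (truth_kind: tandem)
  unit_coding_length: 120      # bp conserved coding region per unit
  nts_length: 180              # bp non-transcribed spacer (100-700 allowed)
  n_units: 15
  per_unit_divergence: 0.01    # substitutions per base, per copy
  flank_lengths: [40, 45]

construct:
  unprotected_offset: 87       # bp between blunt cut and insert
  protected_offset: 8          # bp between insert and protective cut

schedule:                      # exonuclease III timing
  rate_bp_per_min: 450.0       # digestion speed at 37 C
  first_time_s: 120.0          # first aliquot: 2 min
  increment_s: 90.0            # each further aliquot 90 s longer
  n_aliquots: 3

digestion:
  n_molecules: 9000            # pool size, split evenly across aliquots
  dispersion_shape: 1.2        # Gamma shape of per-molecule deletion depth

selection:                     # gel / toothpick-assay ladder
  target_spacing_bp: 400.0
  size_noise_sd_bp: 25.0       # gel size-estimation error (0 = noise-free)
  spacing_min_bp: 0.0
  spacing_max_bp: null         # null -> target spacing
  stop_at_read_len: true       # stop once a clone is shorter than one read
  include_full_length: true    # the untreated original clone anchors the ladder

reads:                         # Sanger read model
  length_mean: 700.0
  length_sd: 60.0
  length_min: 550
  length_max: 900
  fixed_length: null           # set (e.g. 500) to bypass the distribution
  error_rate: 0.001            # i.i.d. substitution probability per base

orientation:
  mode: restriction            # restriction (banding assay) | score (overlap)
  recognition_pattern: GGCCNNNNNGGCC   # IUPAC; SfiI-like by default
  left_arm_bp: 10300           # asymmetric vector arms make banding informative
  right_arm_bp: 2200
  inject_site: true            # plant the site near the protected end if absent

assembly:
  min_overlap: 100             # bp; joins below this are contig breaks
  band_bp: null                # offset search half-width; null -> 3*sqrt(2)*gel sd
  mismatch_penalty: 2.0
  tie_tolerance: 0.02          # per-base score window treated as a tie
  min_join_score: 0.5          # best score below this -> contig break
  use_exact_offsets: false     # true = fragment-analyzer deletion sizes available

annotation:
  min_run_bp: 15               # minimum SSR run length
  gap_merge_bp: 10             # merge distance for continuous SSR regions
  min_unit_bp: 50              # smallest tandem-unit period considered
  min_identity: 0.8            # self-identity threshold for unit detection
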