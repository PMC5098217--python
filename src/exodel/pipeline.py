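"""End-to-end campaign orchestration.

``run_pipeline`` wires the stages together: obtain a ground-truth fragment
(synthetic SSR stretch, synthetic tandem array, or a user-supplied
FASTA/GenBank/accession sequence), build the protected/unprotected
construct, run the timed exonuclease digestion, select a ~400 bp deletion
ladder on the gel, call clone orientations, take one Sanger read per clone,
assemble the ordered reads, annotate the consensus, and score it against
the truth.  Every stage draws from an independent substream of one
top-level seed, so a (config, seed) pair reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import assembly as asm
from . import deletion as dl
from . import repeats as rp
from . import seqio
from .errors import InvalidSpecError, OrientationUndecidableError
from .fetch import fetch_accession

log = logging.getLogger("exodel")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "load_config",
    "save_config",
    "preset_config",
    "PRESETS",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SSRTruthParams:
    total_length: int = 7333
    variant_rate: float = 0.01
    blocks: list | None = None            # [[motif, copies], ...] or None -> default mix
    flank_lengths: list | None = None     # [left, right] or None -> default split


@dataclass
class TandemTruthParams:
    unit_coding_length: int = 120
    nts_length: int = 180
    n_units: int = 15
    per_unit_divergence: float = 0.01
    flank_lengths: list = field(default_factory=lambda: [40, 45])


@dataclass
class ConstructParams:
    unprotected_offset: int = 87
    protected_offset: int = 8


@dataclass
class ScheduleParams:
    rate_bp_per_min: float = 450.0
    first_time_s: float = 120.0
    increment_s: float = 90.0
    n_aliquots: int = 3


@dataclass
class DigestionParams:
    n_molecules: int = 9000
    dispersion_shape: float = 1.2


@dataclass
class SelectionParams:
    target_spacing_bp: float = 400.0
    # gel size-estimation noise; kept small enough that a deletion step
    # rarely exceeds the read length (such a step is an undetectable
    # coverage gap that tandem periodicity can silently paper over)
    size_noise_sd_bp: float = 25.0
    spacing_min_bp: float = 0.0
    spacing_max_bp: float | None = None   # None -> target spacing
    stop_at_read_len: bool = True
    include_full_length: bool = True


@dataclass
class ReadParams:
    length_mean: float = 700.0
    length_sd: float = 60.0
    length_min: int = 550
    length_max: int = 900
    fixed_length: int | None = None
    # post-trim high-quality Sanger base-call error rate
    error_rate: float = 0.001

    def model(self) -> dl.ReadLengthModel:
        return dl.ReadLengthModel(self.length_mean, self.length_sd,
                                  self.length_min, self.length_max,
                                  self.fixed_length)


@dataclass
class OrientationParams:
    mode: str = "restriction"             # restriction | score
    recognition_pattern: str = "GGCCNNNNNGGCC"
    left_arm_bp: int = 10300
    right_arm_bp: int = 2200
    inject_site: bool = True              # plant the site in the protected-side flank


@dataclass
class AssemblyParams:
    min_overlap: int = 100
    band_bp: int | None = None            # None -> 3 x gel size noise sd
    mismatch_penalty: float = 2.0
    # scores within this tolerance are treated as tied and passed to the
    # anchor / exact-size resolution; covers read-error score jitter
    tie_tolerance: float = 0.02
    min_join_score: float = 0.5
    use_exact_offsets: bool = False       # fragment-analyzer exact deletion sizes


@dataclass
class AnnotationParams:
    min_run_bp: int = 15
    gap_merge_bp: int = 10
    min_unit_bp: int = 50
    min_identity: float = 0.8


@dataclass
class PipelineConfig:
    """Full campaign configuration; exactly one truth source is active,
    chosen by ``truth_kind``."""

    seed: int = 0
    output_dir: str = "exodel-out"
    truth_kind: str = "ssr"               # ssr | tandem | fasta | genbank | accession
    truth_path: str | None = None
    accession: str | None = None
    ssr: SSRTruthParams = field(default_factory=SSRTruthParams)
    tandem: TandemTruthParams = field(default_factory=TandemTruthParams)
    construct: ConstructParams = field(default_factory=ConstructParams)
    schedule: ScheduleParams = field(default_factory=ScheduleParams)
    digestion: DigestionParams = field(default_factory=DigestionParams)
    selection: SelectionParams = field(default_factory=SelectionParams)
    reads: ReadParams = field(default_factory=ReadParams)
    orientation: OrientationParams = field(default_factory=OrientationParams)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)

    def __post_init__(self) -> None:
        kinds = ("ssr", "tandem", "fasta", "genbank", "accession")
        if self.truth_kind not in kinds:
            raise InvalidSpecError(f"truth_kind must be one of {kinds}")
        if self.truth_kind in ("fasta", "genbank") and not self.truth_path:
            raise InvalidSpecError(f"truth_kind={self.truth_kind} needs truth_path")
        if self.truth_kind == "accession" and not self.accession:
            raise InvalidSpecError("truth_kind=accession needs an accession id")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = dict(data)
        for name, sub in [("ssr", SSRTruthParams), ("tandem", TandemTruthParams),
                          ("construct", ConstructParams), ("schedule", ScheduleParams),
                          ("digestion", DigestionParams), ("selection", SelectionParams),
                          ("reads", ReadParams), ("orientation", OrientationParams),
                          ("assembly", AssemblyParams), ("annotation", AnnotationParams)]:
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = sub(**kwargs[name])
        return cls(**kwargs)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def preset_config(name: str, seed: int = 0,
                  output_dir: str | None = None) -> PipelineConfig:
    """Named campaign presets.

    ``ssr-campaign``: a ~7.3 kb fragment with an uninterrupted ~6.2 kb
    trinucleotide-repeat region (five motifs), sequenced end to end.
    ``5s-campaign``: a 4585 bp tandem array of 15 copies of a 120 bp
    coding region plus 180 bp spacer.
    """
    if name not in PRESETS:
        raise InvalidSpecError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    config = PRESETS[name](seed)
    if output_dir is not None:
        config.output_dir = output_dir
    return config


def _ssr_preset(seed: int) -> PipelineConfig:
    return PipelineConfig(seed=seed, truth_kind="ssr",
                          output_dir="exodel-out/ssr-campaign")


def _tandem_preset(seed: int) -> PipelineConfig:
    return PipelineConfig(seed=seed, truth_kind="tandem",
                          output_dir="exodel-out/5s-campaign")


PRESETS = {"ssr-campaign": _ssr_preset, "5s-campaign": _tandem_preset}


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    config: PipelineConfig
    truth: rp.AnnotatedSequence
    construct: dl.Construct
    ladder: dl.CloneLadder
    reads: list[dl.SangerRead]
    orientations_called: list[str | None]
    read_set: asm.OrderedReadSet
    assembly: asm.AssemblyResult
    evaluation: asm.EvaluationReport
    consensus_annotation: rp.AnnotatedSequence
    continuous_regions: list[tuple[int, int]]
    artifacts: dict[str, str]


def _load_truth(config: PipelineConfig, seed: int) -> rp.AnnotatedSequence:
    kind = config.truth_kind
    if kind == "ssr":
        p = config.ssr
        if p.blocks is None:
            spec = rp.default_ssr_spec(seed=seed, total_length=p.total_length,
                                       variant_rate=p.variant_rate)
        else:
            blocks = tuple((m, int(c)) for m, c in p.blocks)
            if p.flank_lengths is None:
                rep = sum(len(m) * c for m, c in blocks)
                rest = p.total_length - rep
                flanks = (rest // 2, rest - rest // 2)
            else:
                flanks = tuple(p.flank_lengths)
            spec = rp.SSRFragmentSpec(total_length=p.total_length, blocks=blocks,
                                      variant_rate=p.variant_rate,
                                      flank_lengths=flanks, seed=seed)
        return rp.generate_ssr_fragment(spec)
    if kind == "tandem":
        p = config.tandem
        spec = rp.TandemArraySpec(unit_coding_length=p.unit_coding_length,
                                  nts_length=p.nts_length, n_units=p.n_units,
                                  per_unit_divergence=p.per_unit_divergence,
                                  flank_lengths=tuple(p.flank_lengths), seed=seed)
        return rp.generate_tandem_array_fragment(spec)
    if kind == "fasta":
        return seqio.read_fasta(config.truth_path)
    if kind == "genbank":
        return seqio.read_genbank(config.truth_path)
    return fetch_accession(config.accession)


def _inject_site(truth: rp.AnnotatedSequence, pattern: str,
                 rng: np.random.Generator) -> rp.AnnotatedSequence:
    """Plant the orientation-assay recognition site near the protected end
    of the insert (retained by every deletion clone) unless already present."""
    seq = truth.sequence
    if dl.restriction_bands(seq, pattern) != (len(seq),):
        return truth  # a site already exists somewhere in the insert
    site = "".join(b if b != "N" else rp.BASES[rng.integers(0, 4)]
                   for b in pattern.upper())
    pos = max(0, len(seq) - len(site) - 20)
    truth.sequence = seq[:pos] + site + seq[pos + len(site):]
    return truth


def _random_arm(rng: np.random.Generator, n: int) -> str:
    letters = np.array(list(rp.BASES))
    return "".join(letters[rng.integers(0, 4, size=n)])


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute the full simulated sequencing campaign.

    Stages: truth -> construct -> digestion -> gel selection -> orientation
    -> reads -> assembly -> annotation -> evaluation.  Intermediate
    artifacts are written to ``config.output_dir`` when ``write_outputs``.
    Fully reproducible from (config, seed).
    """
    t0 = time.perf_counter()
    ss = np.random.SeedSequence(config.seed)
    (ss_truth, ss_pads, ss_digest, ss_select, ss_reads,
     ss_arms, ss_site) = ss.spawn(7)
    truth_seed = int(ss_truth.generate_state(1, np.uint32)[0] % (2**31))

    def stage(name: str, start: float) -> float:
        now = time.perf_counter()
        log.info("stage %-12s %6.2f s", name, now - start)
        return now

    truth = _load_truth(config, truth_seed)
    if config.orientation.mode == "restriction" and config.orientation.inject_site:
        truth = _inject_site(truth, config.orientation.recognition_pattern,
                             np.random.default_rng(ss_site))
    t = stage("truth", t0)

    pad_rng = np.random.default_rng(ss_pads)
    construct = dl.Construct.from_insert(
        truth, unprotected_offset=config.construct.unprotected_offset,
        protected_offset=config.construct.protected_offset,
        seed=int(pad_rng.integers(0, 2**31)))
    schedule = dl.DigestionSchedule(
        rate_bp_per_min=config.schedule.rate_bp_per_min,
        first_time_s=config.schedule.first_time_s,
        increment_s=config.schedule.increment_s,
        n_aliquots=config.schedule.n_aliquots)

    pool = dl.simulate_exonuclease_digestion(
        construct, schedule, n_molecules=config.digestion.n_molecules,
        dispersion_shape=config.digestion.dispersion_shape,
        seed=np.random.default_rng(ss_digest))
    t = stage("digestion", t)

    read_model = config.reads.model()
    stop_len = (min(read_model.minimum, read_model.fixed or read_model.minimum)
                if config.selection.stop_at_read_len else None)
    ladder = dl.simulate_gel_size_selection(
        pool, target_spacing_bp=config.selection.target_spacing_bp,
        size_noise_sd_bp=config.selection.size_noise_sd_bp,
        full_insert_len=len(construct),
        seed=np.random.default_rng(ss_select),
        spacing_min_bp=config.selection.spacing_min_bp,
        spacing_max_bp=config.selection.spacing_max_bp,
        stop_len_bp=stop_len,
        include_full_length=config.selection.include_full_length)
    t = stage("selection", t)

    orientations_called: list[str | None] = []
    if config.orientation.mode == "restriction":
        arm_rng = np.random.default_rng(ss_arms)
        left_arm = _random_arm(arm_rng, config.orientation.left_arm_bp)
        right_arm = _random_arm(arm_rng, config.orientation.right_arm_bp)
        for entry in ladder.selected:
            try:
                called = dl.call_orientation(
                    entry.molecule.remaining_sequence, entry.orientation,
                    config.orientation.recognition_pattern, left_arm, right_arm)
            except OrientationUndecidableError:
                called = None  # fall back to neighbour scoring for this clone
            orientations_called.append(called)
    else:
        orientations_called = [None] * len(ladder.selected)
    t = stage("orientation", t)

    read_streams = ss_reads.spawn(len(ladder.selected))
    reads = [dl.simulate_sanger_read(entry, i, read_length=read_model,
                                     error_rate=config.reads.error_rate,
                                     seed=np.random.default_rng(read_streams[i]))
             for i, entry in enumerate(ladder.selected)]
    t = stage("reads", t)

    # an offset estimate is the difference of two noisy gel sizes, so its
    # sd is sqrt(2) x the per-clone size noise; the band covers 3 sd of it
    band = (config.assembly.band_bp if config.assembly.band_bp is not None
            else int(np.ceil(3 * np.sqrt(2) * config.selection.size_noise_sd_bp)))
    exact_offsets = None
    if config.assembly.use_exact_offsets:
        d = ladder.true_deletions
        exact_offsets = [d[i + 1] - d[i] for i in range(len(d) - 1)]
    read_set = asm.orient_reads(reads, ladder.estimated_offsets,
                                orientations=orientations_called,
                                band_bp=band,
                                min_overlap=config.assembly.min_overlap,
                                exact_offsets=exact_offsets)
    result = asm.assemble(read_set, min_overlap=config.assembly.min_overlap,
                          mismatch_penalty=config.assembly.mismatch_penalty,
                          tie_tolerance=config.assembly.tie_tolerance,
                          min_join_score=config.assembly.min_join_score)
    # sanity check an experimenter would make: a complete assembly must
    # match the gel-estimated size of the undeleted clone; a shortfall of a
    # repeat-unit length betrays a collapsed join over a coverage gap
    if len(result.contigs) == 1 and ladder.selected:
        est_full = ladder.selected[0].estimated_size_bp
        tol = 4 * config.selection.size_noise_sd_bp + 20
        if abs(len(result.contigs[0]) - est_full) > tol:
            result.flags.append(
                f"consensus length {len(result.contigs[0])} bp deviates from "
                f"the gel-estimated full-length clone ({est_full:.0f} bp) by "
                f"more than {tol:.0f} bp: a join may have collapsed a repeat "
                f"unit across a coverage gap")
    t = stage("assembly", t)

    evaluation = asm.evaluate_against_truth(result, construct.sequence)

    consensus_seq = result.contigs[0] if result.contigs else ""
    ann = config.annotation
    runs = rp.annotate_ssr_runs(consensus_seq, min_run_bp=ann.min_run_bp)
    regions = rp.continuous_ssr_regions(runs, gap_merge_bp=ann.gap_merge_bp,
                                        sequence=consensus_seq)
    n_units, unit_intervals = rp.count_tandem_units(
        consensus_seq, min_unit_bp=ann.min_unit_bp, min_identity=ann.min_identity)
    consensus_annotation = rp.AnnotatedSequence(
        consensus_seq, ssr_runs=runs, tandem_units=unit_intervals,
        source=f"consensus:{truth.source}")
    t = stage("annotation", t)

    artifacts: dict[str, str] = {}
    if write_outputs:
        artifacts = _write_artifacts(config, truth, construct, ladder, reads,
                                     orientations_called, result, evaluation,
                                     consensus_annotation, regions, n_units)
    stage("total", t0)
    return PipelineResult(config=config, truth=truth, construct=construct,
                          ladder=ladder, reads=reads,
                          orientations_called=orientations_called,
                          read_set=read_set, assembly=result,
                          evaluation=evaluation,
                          consensus_annotation=consensus_annotation,
                          continuous_regions=regions, artifacts=artifacts)


def _write_artifacts(config, truth, construct, ladder, reads, orientations,
                     result, evaluation, consensus_annotation, regions,
                     n_units) -> dict[str, str]:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def mark(name: str, path: Path) -> Path:
        paths[name] = str(path)
        return path

    save_config(config, mark("config", out / "config.yaml"))
    seqio.write_fasta(mark("truth", out / "truth.fasta"),
                      {truth.source: truth.sequence})
    seqio.write_fasta(mark("construct", out / "construct.fasta"),
                      {f"construct:{truth.source}": construct.sequence})
    seqio.write_ladder_tsv(mark("ladder", out / "ladder.tsv"), ladder,
                           [o or "unknown" for o in orientations])
    seqio.write_reads_fastq(mark("reads_fastq", out / "reads.fastq"), reads)
    seqio.write_reads_fasta(mark("reads_fasta", out / "reads.fasta"), reads)
    contigs = {f"contig_{i:02d}": c for i, c in enumerate(result.contigs)}
    seqio.write_fasta(mark("consensus", out / "consensus.fasta"), contigs)
    seqio.write_joins_tsv(mark("joins", out / "joins.tsv"), result.joins)
    ambiguity = {
        "flags": result.flags,
        "n_contigs": len(result.contigs),
        "ambiguous_joins": [
            {"left": j.left_read_index, "right": j.right_read_index,
             "tied_offsets": list(j.tied_offsets), "status": j.status}
            for j in result.joins if j.status != "unique"],
    }
    mark("ambiguity", out / "ambiguity.json").write_text(
        json.dumps(ambiguity, indent=2) + "\n")
    seqio.write_annotation_bed(mark("annotation_bed", out / "annotation.bed"),
                               consensus_annotation)
    seqio.write_annotation_json(mark("annotation_json", out / "annotation.json"),
                                consensus_annotation, regions)
    eval_payload = {
        "identity": evaluation.identity,
        "matches": evaluation.matches,
        "truth_length": evaluation.truth_length,
        "consensus_length": evaluation.consensus_length,
        "n_contigs": evaluation.n_contigs,
        "n_flagged_joins": len(evaluation.flagged_joins),
        "notes": evaluation.notes,
        "n_tandem_units_detected": n_units,
        "continuous_ssr_regions": [list(r) for r in regions],
    }
    mark("evaluation", out / "evaluation.json").write_text(
        json.dumps(eval_payload, indent=2) + "\n")
    manifest = {
        "seed": config.seed,
        "truth_kind": config.truth_kind,
        "truth_source": truth.source,
        "n_clones": len(ladder),
        "n_reads": len(reads),
        "n_contigs": len(result.contigs),
        "identity": evaluation.identity,
        "artifacts": {k: Path(v).name for k, v in sorted(paths.items())},
    }
    mark("manifest", out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
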