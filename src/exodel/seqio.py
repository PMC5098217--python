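"""File formats: FASTA/FASTQ/GenBank via Biopython, plus BED/TSV/JSON
reports for annotations, ladders and joins."""

from __future__ import annotations

import csv
import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .repeats import AnnotatedSequence, MotifRun

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "write_reads_fastq",
    "write_reads_fasta",
    "write_ladder_tsv",
    "read_ladder_tsv",
    "write_annotation_bed",
    "write_annotation_json",
    "write_joins_tsv",
]


def read_fasta(path: str | Path) -> AnnotatedSequence:
    """First record of a FASTA file as an (unannotated) sequence."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return AnnotatedSequence(str(record.seq).upper(), source=record.id)


def read_genbank(path: str | Path) -> AnnotatedSequence:
    """Sequence and accession of a GenBank flat file (features ignored)."""
    record = SeqIO.read(str(path), "genbank")
    return AnnotatedSequence(str(record.seq).upper(), source=record.id)


def write_fasta(path: str | Path, sequences: dict[str, str],
                wrap: int = 70) -> None:
    """Write sequences as FASTA wrapped at ``wrap`` columns (60 or 70 are
    customary)."""
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    with open(path, "w") as handle:
        FastaWriter(handle, wrap=wrap).write_file(records)


def _phred_char(error_rate: float) -> str:
    import math
    q = 40 if error_rate <= 0 else min(40, int(round(-10 * math.log10(error_rate))))
    return chr(q + 33)


def write_reads_fastq(path: str | Path, reads: list, prefix: str = "clone") -> None:
    """Write Sanger reads as FASTQ with a constant Phred quality derived
    from each read's substitution error rate."""
    with open(path, "w") as handle:
        for i, read in enumerate(reads):
            q = _phred_char(read.error_rate)
            handle.write(f"@{prefix}_{i:04d} orientation={read.orientation}\n"
                         f"{read.sequence}\n+\n{q * len(read.sequence)}\n")


def write_reads_fasta(path: str | Path, reads: list, prefix: str = "clone",
                      wrap: int = 70) -> None:
    write_fasta(path, {f"{prefix}_{i:04d}": r.sequence
                       for i, r in enumerate(reads)}, wrap=wrap)


def write_ladder_tsv(path: str | Path, ladder, orientations_called=None) -> None:
    """Ladder manifest: clone index, estimated size, aliquot, orientation."""
    with open(path, "w", newline="") as handle:
        w = csv.writer(handle, delimiter="\t", lineterminator="\n")
        w.writerow(["clone_index", "estimated_size_bp", "aliquot",
                    "orientation_called"])
        for i, entry in enumerate(ladder.selected):
            called = (orientations_called[i] if orientations_called is not None
                      else entry.orientation)
            w.writerow([i, f"{entry.estimated_size_bp:.1f}",
                        entry.molecule.aliquot_index, called])


def read_ladder_tsv(path: str | Path) -> list[dict]:
    with open(path, newline="") as handle:
        return list(csv.DictReader(handle, delimiter="\t"))


def write_annotation_bed(path: str | Path, annotated: AnnotatedSequence,
                         chrom: str | None = None) -> None:
    """SSR runs and tandem units as BED (0-based half-open): chrom, start,
    end, name (motif or "unit"), score (copy count, 0 for units)."""
    chrom = chrom or annotated.source
    with open(path, "w") as handle:
        for run in sorted(annotated.ssr_runs, key=lambda r: r.start):
            handle.write(f"{chrom}\t{run.start}\t{run.end}\t{run.motif}\t"
                         f"{run.copy_count}\n")
        for s, e in annotated.tandem_units:
            handle.write(f"{chrom}\t{s}\t{e}\tunit\t0\n")


def write_annotation_json(path: str | Path, annotated: AnnotatedSequence,
                          continuous_regions: list[tuple[int, int]] | None = None,
                          ) -> None:
    payload = {
        "source": annotated.source,
        "length": len(annotated.sequence),
        "ssr_runs": [
            {"motif": r.motif, "start": r.start, "end": r.end,
             "copy_count": r.copy_count,
             "mismatch_positions": list(r.mismatch_positions)}
            for r in annotated.ssr_runs
        ],
        "tandem_units": [list(u) for u in annotated.tandem_units],
    }
    if continuous_regions is not None:
        payload["continuous_ssr_regions"] = [list(r) for r in continuous_regions]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_joins_tsv(path: str | Path, joins) -> None:
    with open(path, "w", newline="") as handle:
        w = csv.writer(handle, delimiter="\t", lineterminator="\n")
        w.writerow(["left_read", "right_read", "offset_bp", "overlap_len",
                    "mismatches", "status", "tied_offsets"])
        for j in joins:
            w.writerow([j.left_read_index, j.right_read_index, j.chosen_offset,
                        j.overlap_len, j.mismatches_in_overlap, j.status,
                        ",".join(map(str, j.tied_offsets))])
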