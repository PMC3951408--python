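"""Readers and writers for transcript models and candidate tables.

Two input dialects are supported:

* **GenBank flat files** of RefSeq-style mRNA records, where ``exon``
  features partition the transcript and a single-interval ``CDS``
  feature gives the annotated start/stop in transcript coordinates.
* **The toolkit TSV dialect** with columns ``id``, ``sequence``,
  ``exon_lengths`` (comma-separated), ``cds_start``, ``cds_end``
  (1-based inclusive; empty CDS fields mean no annotated CDS).

Records failing the validity filters are counted, not repaired: missing
exon partitioning, a joined/compound CDS location, or a stop codon
coordinate beyond the last exon each increments its own discard counter.

Candidate tables are written as TSV with a stable header and optionally
as BED6 in transcript space (0-based half-open, per the BED convention;
all other coordinates in the package stay 1-based inclusive).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from Bio import SeqIO
from Bio.SeqFeature import CompoundLocation

from nmdscreen.transcript_model import StructuralError, TranscriptModel

TSV_COLUMNS = ["id", "sequence", "exon_lengths", "cds_start", "cds_end"]
CANDIDATE_COLUMNS = ["id", "orf_start", "orf_end", "orf_length", "kozak", "verdict"]


class TranscriptFormat(Enum):
    GENBANK = "genbank"
    TSV = "tsv"


class ParseError(ValueError):
    """A record or line could not be parsed; the message names it."""


@dataclass
class RecordFilterReport:
    """Census of records read and discarded by the validity filters."""

    total_read: int = 0
    discarded_missing_structure: int = 0
    discarded_joint_cds: int = 0
    discarded_stop_after_last_exon: int = 0

    @property
    def retained(self) -> int:
        return self.total_read - (
            self.discarded_missing_structure
            + self.discarded_joint_cds
            + self.discarded_stop_after_last_exon
        )


def read_transcripts(
    path: Union[str, Path],
    format: Union[TranscriptFormat, str] = TranscriptFormat.TSV,
) -> tuple[list[TranscriptModel], RecordFilterReport]:
    """Read transcript models, applying the record-validity filters."""
    fmt = TranscriptFormat(format) if isinstance(format, str) else format
    path = Path(path)
    if fmt is TranscriptFormat.TSV:
        return _read_tsv(path)
    if fmt is TranscriptFormat.GENBANK:
        return _read_genbank(path)
    raise ParseError(f"unknown format {format!r}")


def _read_tsv(path: Path) -> tuple[list[TranscriptModel], RecordFilterReport]:
    report = RecordFilterReport()
    models: list[TranscriptModel] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or [
            c for c in TSV_COLUMNS if c not in reader.fieldnames
        ]:
            raise ParseError(f"{path}: header must contain columns {TSV_COLUMNS}")
        for lineno, row in enumerate(reader, start=2):
            report.total_read += 1
            try:
                exon_lengths = tuple(
                    int(x) for x in row["exon_lengths"].split(",") if x.strip()
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad exon_lengths") from exc
            if not exon_lengths:
                report.discarded_missing_structure += 1
                continue
            cds_start = int(row["cds_start"]) if row["cds_start"].strip() else None
            cds_end = int(row["cds_end"]) if row["cds_end"].strip() else None
            seq = row["sequence"].strip().upper()
            if cds_end is not None and cds_end > len(seq):
                report.discarded_stop_after_last_exon += 1
                continue
            try:
                models.append(
                    TranscriptModel(
                        id=row["id"],
                        sequence=seq,
                        exon_lengths=exon_lengths,
                        cds_start=cds_start,
                        cds_end=cds_end,
                    )
                )
            except StructuralError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return models, report


def _read_genbank(path: Path) -> tuple[list[TranscriptModel], RecordFilterReport]:
    report = RecordFilterReport()
    models: list[TranscriptModel] = []
    for record in SeqIO.parse(str(path), "genbank"):
        report.total_read += 1
        exon_feats = [f for f in record.features if f.type == "exon"]
        cds_feats = [f for f in record.features if f.type == "CDS"]
        if not exon_feats:
            report.discarded_missing_structure += 1
            continue
        if any(isinstance(f.location, CompoundLocation) for f in cds_feats):
            report.discarded_joint_cds += 1
            continue
        exon_lengths = tuple(
            int(f.location.end) - int(f.location.start) for f in exon_feats
        )
        cds_start = cds_end = None
        if cds_feats:
            loc = cds_feats[0].location
            cds_start = int(loc.start) + 1  # GenBank parser is 0-based half-open
            cds_end = int(loc.end)
        if cds_end is not None and cds_end > len(record.seq):
            report.discarded_stop_after_last_exon += 1
            continue
        try:
            models.append(
                TranscriptModel(
                    id=record.id,
                    sequence=str(record.seq).upper(),
                    exon_lengths=exon_lengths,
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
        except StructuralError:
            report.discarded_missing_structure += 1
    return models, report


def write_transcripts(
    models: Iterable[TranscriptModel], path: Union[str, Path]
) -> None:
    """Write transcript models in the toolkit TSV dialect."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for t in models:
            writer.writerow(
                [
                    t.id,
                    t.sequence,
                    ",".join(str(e) for e in t.exon_lengths),
                    "" if t.cds_start is None else t.cds_start,
                    "" if t.cds_end is None else t.cds_end,
                ]
            )


@dataclass(frozen=True)
class CandidateRow:
    """One candidate ORF with its verdict, as written to the TSV/BED."""

    id: str
    orf_start: int
    orf_end: int
    kozak: bool = False
    verdict: str = ""

    @property
    def orf_length(self) -> int:
        return self.orf_end - self.orf_start + 1


def write_candidates(
    rows: Sequence[CandidateRow],
    path: Union[str, Path],
    bed_path: Optional[Union[str, Path]] = None,
) -> None:
    """Write candidate rows as TSV, optionally also as transcript-space BED6.

    BED lines use 0-based half-open coordinates (``74..184`` becomes
    ``73\t184``); scores are 0 and strand is ``+`` (spliced mRNAs are
    single-stranded 5'->3').
    """
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CANDIDATE_COLUMNS)
        for r in rows:
            writer.writerow(
                [r.id, r.orf_start, r.orf_end, r.orf_length, int(r.kozak), r.verdict]
            )
    if bed_path is not None:
        with Path(bed_path).open("w", newline="") as fh:
            for r in rows:
                name = f"{r.id}:{r.orf_start}..{r.orf_end}"
                fh.write(
                    f"{r.id}\t{r.orf_start - 1}\t{r.orf_end}\t{name}\t0\t+\n"
                )


def read_candidates(path: Union[str, Path]) -> list[CandidateRow]:
    """Read back a candidate TSV written by :func:`write_candidates`."""
    rows: list[CandidateRow] = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rows.append(
                CandidateRow(
                    id=row["id"],
                    orf_start=int(row["orf_start"]),
                    orf_end=int(row["orf_end"]),
                    kozak=bool(int(row["kozak"])),
                    verdict=row["verdict"],
                )
            )
    return rows
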