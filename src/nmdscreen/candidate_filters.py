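"""Decision rules separating functional candidate ORFs from artifacts.

Three orthogonal lines of evidence are combined:

* **nucleotide self-similarity** — a candidate ORF highly similar to
  the annotated CDS of its own gene (including splice isoforms) most
  likely arose by gene rearrangement and is discarded;
* **protein-level evidence** — similarity of the ORF-encoded protein to
  known proteins, judged on the positive-residue ratio or the aligned
  fraction of the ORF protein;
* **domain evidence** — annotated protein domains, where a signal
  peptide or a transmembrane region alone is deemed insufficient
  (subcellular-localization prediction is too unreliable to carry a
  functional call by itself).

All verdicts operate on parsed hit/domain records supplied by any
backend (typically TSV tables from local alignment or domain-scan
runs); this module never invokes external tools.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence, Union

EVALUE_CUTOFF = 1.0e-6
COVERAGE_CUTOFF = 0.5
POSITIVE_RATIO_CUTOFF = 0.5
ALIGN_RATIO_CUTOFF = 0.8


class SimilarityVerdict(Enum):
    DISCARD = "discard"
    KEEP = "keep"


class DomainVerdict(Enum):
    SUFFICIENT = "sufficient"
    INSUFFICIENT = "insufficient"
    NONE = "none"


class DomainClass(Enum):
    SIGNAL_PEPTIDE = "signal_peptide"
    TRANSMEMBRANE = "transmembrane"
    OTHER = "other"


@dataclass(frozen=True)
class NucleotideHit:
    """One nucleotide-level alignment of a candidate ORF to a CDS."""

    query_id: str
    subject_gene_id: str
    evalue: float
    coverage_fraction: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ProteinHit:
    """One protein-level alignment of the ORF-encoded protein."""

    positives: int
    align_length: int
    orf_protein_length: int

    def __post_init__(self) -> None:
        if min(self.positives, self.align_length, self.orf_protein_length) < 0:
            raise ValueError("counts must be non-negative")
        if self.positives > self.align_length:
            raise ValueError("positives cannot exceed align_length")


@dataclass(frozen=True)
class DomainAnnotation:
    """A protein domain annotation with its residue span."""

    domain_class: DomainClass
    identifier: str = ""
    span: tuple[int, int] = (0, 0)


def self_similarity_verdict(
    hits: Sequence[NucleotideHit],
    own_gene_id: str,
    evalue_cutoff: float = EVALUE_CUTOFF,
    coverage_cutoff: float = COVERAGE_CUTOFF,
) -> SimilarityVerdict:
    """DISCARD iff any same-gene hit is significant and well-covered.

    A hit counts against the candidate when ``evalue <= evalue_cutoff``
    AND ``coverage_fraction >= coverage_cutoff``; weaker hits leave the
    candidate in play (KEEP).
    """
    for h in hits:
        if h.subject_gene_id != own_gene_id:
            continue
        if h.evalue <= evalue_cutoff and h.coverage_fraction >= coverage_cutoff:
            return SimilarityVerdict.DISCARD
    return SimilarityVerdict.KEEP


def protein_evidence_verdict(
    hits: Sequence[ProteinHit],
    positive_ratio_cutoff: float = POSITIVE_RATIO_CUTOFF,
    align_ratio_cutoff: float = ALIGN_RATIO_CUTOFF,
) -> bool:
    """True iff any hit exceeds the positive-ratio or align-ratio cutoff.

    Both comparisons are strict: ``positives / orf_protein_length >
    positive_ratio_cutoff`` OR ``align_length / orf_protein_length >
    align_ratio_cutoff``.
    """
    for h in hits:
        if h.orf_protein_length <= 0:
            raise ValueError("orf_protein_length must be positive")
        if (
            h.positives / h.orf_protein_length > positive_ratio_cutoff
            or h.align_length / h.orf_protein_length > align_ratio_cutoff
        ):
            return True
    return False


def domain_evidence_verdict(
    domains: Sequence[DomainAnnotation],
) -> DomainVerdict:
    """Judge domain annotations: any non-localization domain suffices.

    NONE for an empty list; INSUFFICIENT when only signal-peptide and/or
    transmembrane annotations are present; SUFFICIENT when at least one
    other domain class appears.
    """
    if not domains:
        return DomainVerdict.NONE
    if any(d.domain_class is DomainClass.OTHER for d in domains):
        return DomainVerdict.SUFFICIENT
    return DomainVerdict.INSUFFICIENT


def candidate_verdict(
    similarity: SimilarityVerdict,
    protein_evidence: bool,
    domain_evidence: DomainVerdict,
    kozak: bool,
) -> bool:
    """Final call on a candidate functional ORF.

    True iff the candidate survives the self-similarity gate, has a
    positive Kozak context, and carries protein-level evidence OR
    sufficient domain evidence (or both).
    """
    return (
        similarity is SimilarityVerdict.KEEP
        and kozak
        and (protein_evidence or domain_evidence is DomainVerdict.SUFFICIENT)
    )


def read_nucleotide_hits(path: Union[str, Path]) -> list[NucleotideHit]:
    """Read a hit TSV: query_id, subject_gene_id, evalue, coverage_fraction."""
    hits: list[NucleotideHit] = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            hits.append(
                NucleotideHit(
                    query_id=row["query_id"],
                    subject_gene_id=row["subject_gene_id"],
                    evalue=float(row["evalue"]),
                    coverage_fraction=float(row["coverage_fraction"]),
                )
            )
    return hits


def read_protein_hits(path: Union[str, Path]) -> list[ProteinHit]:
    """Read a protein-hit TSV: positives, align_length, orf_protein_length."""
    hits: list[ProteinHit] = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            hits.append(
                ProteinHit(
                    positives=int(row["positives"]),
                    align_length=int(row["align_length"]),
                    orf_protein_length=int(row["orf_protein_length"]),
                )
            )
    return hits


def read_domains(path: Union[str, Path]) -> list[DomainAnnotation]:
    """Read a domain TSV: domain_class, identifier, span_start, span_end."""
    domains: list[DomainAnnotation] = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            domains.append(
                DomainAnnotation(
                    domain_class=DomainClass(row["domain_class"]),
                    identifier=row.get("identifier", ""),
                    span=(int(row.get("span_start", 0)), int(row.get("span_end", 0))),
                )
            )
    return domains
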