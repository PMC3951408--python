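"""Core data types and coordinate arithmetic for spliced transcripts.

Every coordinate in this package is a 1-based inclusive position on the
spliced mRNA (5'->3'). ORF intervals include the stop codon, so an ORF
annotated ``74..184`` has length 111 nt. Genomic coordinates are never
used; exon structure enters only as an ordered list of exon lengths.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

VALID_BASES = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class StructuralError(ValueError):
    """A transcript record violates a structural invariant."""


class CoordinateError(ValueError):
    """A coordinate pair or interval is out of bounds or inverted."""


class Region(Enum):
    """Where an ORF lies relative to the annotated CDS."""

    FIVE_PRIME_UTR = "five_prime_utr"
    THREE_PRIME_UTR = "three_prime_utr"
    ANNOTATED_CDS = "annotated_cds"


class NmdStatus(Enum):
    ELICITING = "eliciting"
    IMMUNE = "immune"


class VerdictBasis(Enum):
    CLASSIC_3PRIME = "classic_3prime"
    FIVE_PRIME_EXTENDED = "five_prime_extended"


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced mRNA with its exon partition and annotated CDS.

    Parameters
    ----------
    id
        Accession string (e.g. ``NM_018848``).
    sequence
        Spliced nucleotide sequence over {A, C, G, T, N}, 5'->3'.
    exon_lengths
        Ordered exon lengths in nucleotides; must sum to ``len(sequence)``.
    cds_start
        1-based position of the A of the annotated ATG, or ``None``.
    cds_end
        1-based position of the 3'-most nucleotide of the annotated stop
        codon, or ``None``.
    validated
        When true, the start codon is checked to actually read ``ATG``.
    """

    id: str
    sequence: str
    exon_lengths: tuple[int, ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    validated: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "exon_lengths", tuple(self.exon_lengths))
        if not self.exon_lengths:
            raise StructuralError(f"{self.id}: empty exon list")
        if any(e <= 0 for e in self.exon_lengths):
            raise StructuralError(f"{self.id}: non-positive exon length")
        if sum(self.exon_lengths) != len(self.sequence):
            raise StructuralError(
                f"{self.id}: exon lengths sum to {sum(self.exon_lengths)} "
                f"but sequence has {len(self.sequence)} nt"
            )
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise StructuralError(f"{self.id}: invalid bases {sorted(bad)}")
        if (self.cds_start is None) != (self.cds_end is None):
            raise StructuralError(f"{self.id}: cds_start/cds_end must be set together")
        if self.cds_start is not None:
            assert self.cds_end is not None
            if not (1 <= self.cds_start < self.cds_end <= len(self.sequence)):
                raise StructuralError(
                    f"{self.id}: CDS {self.cds_start}..{self.cds_end} outside "
                    f"transcript of {len(self.sequence)} nt"
                )
            if (self.cds_end - self.cds_start + 1) % 3 != 0:
                raise StructuralError(f"{self.id}: CDS length not divisible by 3")
            if self.validated:
                codon = self.sequence[self.cds_start - 1 : self.cds_start + 2]
                if codon != "ATG":
                    raise StructuralError(
                        f"{self.id}: validated record does not start with ATG ({codon})"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_exons(self) -> int:
        return len(self.exon_lengths)

    def base(self, pos: int) -> str:
        """Nucleotide at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.sequence):
            raise CoordinateError(f"position {pos} outside 1..{len(self.sequence)}")
        return self.sequence[pos - 1]

    def slice(self, start: int, end: int) -> str:
        """Subsequence for the 1-based inclusive interval ``start..end``."""
        if start > end:
            raise CoordinateError(f"inverted interval {start}..{end}")
        if start < 1 or end > len(self.sequence):
            raise CoordinateError(
                f"interval {start}..{end} outside 1..{len(self.sequence)}"
            )
        return self.sequence[start - 1 : end]

    def exon_of(self, pos: int) -> int:
        """1-based ordinal of the exon containing position ``pos``."""
        if not 1 <= pos <= len(self.sequence):
            raise CoordinateError(f"position {pos} outside 1..{len(self.sequence)}")
        cum = 0
        for i, length in enumerate(self.exon_lengths, start=1):
            cum += length
            if pos <= cum:
                return i
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class JunctionSet:
    """Exon-exon junction coordinates of one transcript.

    Each position is the last nucleotide of a non-terminal exon; junction
    k lies between ``positions[k]`` and ``positions[k] + 1``.
    """

    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", tuple(self.positions))
        if any(b <= a for a, b in itertools.pairwise(self.positions)):
            raise StructuralError("junction positions must be strictly increasing")

    def __iter__(self):
        return iter(self.positions)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def terminal(self) -> Optional[int]:
        """The 3'-most junction, or ``None`` for a single-exon transcript."""
        return self.positions[-1] if self.positions else None


@dataclass(frozen=True)
class OrfCall:
    """An ATG-to-stop interval in one reading frame.

    The interval includes the stop codon: ``end`` is the 3'-most
    nucleotide of TAA/TAG/TGA, so ``end - start + 1`` is a multiple of 3
    and at least 6 (one codon plus the stop).
    """

    start: int
    end: int
    frame: int
    kozak_positive: bool = False
    region: Region = Region.THREE_PRIME_UTR

    def __post_init__(self) -> None:
        length = self.end - self.start + 1
        if length < 6 or length % 3 != 0:
            raise CoordinateError(
                f"ORF {self.start}..{self.end}: length {length} invalid "
                "(must be >= 6 and divisible by 3)"
            )
        if self.frame != (self.start - 1) % 3:
            raise CoordinateError(
                f"ORF {self.start}..{self.end}: frame {self.frame} != "
                f"{(self.start - 1) % 3}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class NmdVerdict:
    """Outcome of an NMD-architecture classification."""

    status: NmdStatus
    basis: VerdictBasis
    stop_to_terminal_junction: Optional[int] = None
    unneutralized_junctions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "unneutralized_junctions", tuple(self.unneutralized_junctions)
        )
        immune = self.status is NmdStatus.IMMUNE
        if immune != (len(self.unneutralized_junctions) == 0):
            raise StructuralError(
                "IMMUNE verdict requires an empty unneutralized-junction list"
            )


@dataclass(frozen=True)
class RescueUnit:
    """A set of ORFs that jointly neutralize all required junctions."""

    orfs: tuple[OrfCall, ...]
    neutralized_junctions: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "orfs", tuple(self.orfs))
        object.__setattr__(
            self, "neutralized_junctions", tuple(self.neutralized_junctions)
        )
        starts = [o.start for o in self.orfs]
        if starts != sorted(starts):
            raise StructuralError("rescue-unit ORFs must be ordered by start")

    @property
    def total_orf_length(self) -> int:
        return sum(o.length for o in self.orfs)


def junctions(t: TranscriptModel) -> JunctionSet:
    """Exon-exon junction coordinates as prefix sums of exon lengths.

    The final exon contributes no junction; a single-exon transcript
    yields an empty set.
    """
    positions = tuple(itertools.accumulate(t.exon_lengths))[:-1]
    return JunctionSet(positions)


def orf_length(start: int, end: int) -> int:
    """Length in nt of the 1-based inclusive interval ``start..end``."""
    if start > end:
        raise CoordinateError(f"start {start} > end {end}")
    return end - start + 1


def stop_junction_distance(t: TranscriptModel) -> int:
    """Distance from the annotated stop to the terminal exon-exon junction.

    Returns ``terminal_junction - cds_end``; negative values mean the
    stop codon lies inside the terminal exon.

    Raises
    ------
    StructuralError
        If the transcript has a single exon (no junction exists); callers
        treat that architecture as NMD-immune.
    CoordinateError
        If the transcript has no annotated CDS.
    """
    if t.cds_end is None:
        raise CoordinateError(f"{t.id}: no annotated CDS")
    terminal = junctions(t).terminal
    if terminal is None:
        raise StructuralError(f"{t.id}: single-exon transcript has no junction")
    return terminal - t.cds_end
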