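"""The 55-nucleotide-rule classifier and its 5'-UTR extension.

During splicing an exon junction complex (EJC) is deposited ~20-24 nt
upstream of every exon-exon junction; the pioneer round of translation
removes EJCs over the region the ribosome traverses. A stop codon whose
3'-most base lies more than 55 nt upstream of the terminal junction
leaves at least one EJC in place and elicits NMD. This module implements
that rule, the search for 3'-UTR "rescuing" ORFs whose translation would
neutralize the remaining junctions, the analogous 5'-UTR architecture
classification for uORF-bearing transcripts, and the per-exon census of
annotated start codons.

The operative predicate throughout is the pure 55-nt window: an ORF
neutralizes a junction iff it starts at or upstream of the junction and
ends no more than ``threshold`` nt upstream of it. ORFs starting
downstream of a junction never neutralize it, and scanning between
sequential uORFs is not modeled.
"""

from __future__ import annotations

import itertools
from bisect import bisect_left
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import pandas as pd

from nmdscreen.transcript_model import (
    CoordinateError,
    NmdStatus,
    NmdVerdict,
    OrfCall,
    Region,
    RescueUnit,
    StructuralError,
    TranscriptModel,
    VerdictBasis,
    junctions,
    stop_junction_distance,
)
from nmdscreen.orf_scanner import scan_orfs

DEFAULT_THRESHOLD = 55  # nt, the 55-nucleotide rule window
DEFAULT_MIN_UORF_LENGTH = 99  # nt; functional uORF candidates must exceed this


class FivePrimeClass(Enum):
    """5'-UTR architecture classes for transcripts with an annotated CDS."""

    ATG_IN_FIRST_EXON = "atg_in_first_exon"
    NO_UORF = "no_uorf"
    UORF_IMMUNE = "uorf_immune"
    UORF_ELICITING = "uorf_eliciting"


def classify_classic(
    t: TranscriptModel, threshold: int = DEFAULT_THRESHOLD, strict: bool = True
) -> NmdVerdict:
    """Classic 55-nt-rule verdict from the annotated stop codon.

    ELICITING iff the stop's distance to the terminal junction exceeds
    ``threshold`` (``>=`` when ``strict=False``). Stops in the terminal
    exon, stops within the window, and single-exon transcripts are
    IMMUNE.
    """
    if t.cds_end is None:
        raise CoordinateError(f"{t.id}: cannot classify without an annotated CDS")
    try:
        dist = stop_junction_distance(t)
    except StructuralError:
        return NmdVerdict(
            status=NmdStatus.IMMUNE,
            basis=VerdictBasis.CLASSIC_3PRIME,
            stop_to_terminal_junction=None,
        )
    eliciting = dist > threshold if strict else dist >= threshold
    if not eliciting:
        return NmdVerdict(
            status=NmdStatus.IMMUNE,
            basis=VerdictBasis.CLASSIC_3PRIME,
            stop_to_terminal_junction=dist,
        )
    junc = junctions(t)
    unneutralized = tuple(j for j in junc if j > t.cds_end)
    return NmdVerdict(
        status=NmdStatus.ELICITING,
        basis=VerdictBasis.CLASSIC_3PRIME,
        stop_to_terminal_junction=dist,
        unneutralized_junctions=unneutralized,
    )


def neutralizes(orf: OrfCall, junction: int, threshold: int = DEFAULT_THRESHOLD) -> bool:
    """Whether translating ``orf`` removes the EJC of ``junction``.

    True iff the ORF starts at or upstream of the junction and its stop
    lies no more than ``threshold`` nt upstream of it — i.e. the ribosome
    either reads across the junction or terminates inside the immunity
    window. An ORF starting downstream of the junction never neutralizes
    it.
    """
    return orf.start <= junction and orf.end >= junction - threshold


def _covering_units(
    orfs: Sequence[OrfCall],
    required: Sequence[int],
    threshold: int,
    max_unit_size: int = 3,
) -> list[RescueUnit]:
    """Minimal (by set inclusion) ORF subsets neutralizing every junction.

    Units are capped at ``max_unit_size`` ORFs; ordering is by unit size,
    then total ORF length, then 5'-most start.
    """
    useful = [o for o in orfs if any(neutralizes(o, j, threshold) for j in required)]
    units: list[tuple[frozenset[int], RescueUnit]] = []
    for size in range(1, min(max_unit_size, len(useful)) + 1):
        for combo in itertools.combinations(range(len(useful)), size):
            members = [useful[i] for i in combo]
            if not all(
                any(neutralizes(o, j, threshold) for o in members) for j in required
            ):
                continue
            key = frozenset(combo)
            if any(prev <= key for prev, _ in units):
                continue  # a subset already covers: not minimal
            units.append(
                (
                    key,
                    RescueUnit(
                        orfs=tuple(sorted(members, key=lambda o: (o.start, o.end))),
                        neutralized_junctions=tuple(required),
                    ),
                )
            )
    result = [u for _, u in units]
    result.sort(
        key=lambda u: (
            len(u.orfs),
            u.total_orf_length,
            u.orfs[0].start if u.orfs else 0,
        )
    )
    return result


def find_rescue_units(
    t: TranscriptModel,
    threshold: int = DEFAULT_THRESHOLD,
    min_orf_length: int = 6,
    strict: bool = True,
) -> list[RescueUnit]:
    """Search the 3' UTR for ORF sets that would rescue the transcript.

    Scans ``cds_end + 1 .. end`` (no overlap with the annotated CDS is
    permitted) and returns every minimal set of ORFs such that each
    exon-exon junction strictly downstream of the stop codon is
    neutralized by at least one member. Multiple ORFs required jointly
    are returned as one unit. An already-immune transcript yields an
    empty list.
    """
    verdict = classify_classic(t, threshold=threshold, strict=strict)
    if verdict.status is NmdStatus.IMMUNE:
        return []
    assert t.cds_end is not None
    utr_start = t.cds_end + 1
    if utr_start + 5 > len(t):
        return []
    orfs = scan_orfs(
        t,
        region=(utr_start, len(t)),
        min_length=min_orf_length,
        orf_region=Region.THREE_PRIME_UTR,
    )
    required = [j for j in junctions(t) if j > t.cds_end]
    return _covering_units(orfs, required, threshold)


def classify_five_prime(
    t: TranscriptModel,
    threshold: int = DEFAULT_THRESHOLD,
    min_uorf_length: int = 6,
) -> FivePrimeClass:
    """Classify the 5'-UTR architecture of a transcript.

    * ``ATG_IN_FIRST_EXON`` — the annotated start sits in exon 1 (no
      EJC can remain upstream of the CDS).
    * ``NO_UORF`` — the 5' UTR contains no ORF: the scanning 43S
      pre-initiation complex traverses the whole UTR to the annotated
      ATG, detaching every deposited EJC.
    * ``UORF_IMMUNE`` — uORFs exist and every junction between the end
      of the FIRST uORF and the annotated ATG is neutralized by some
      uORF. Junctions upstream of the first uORF's stop are cleared by
      scanning; junctions at/after the annotated start belong to the
      annotated CDS.
    * ``UORF_ELICITING`` — uORFs exist but at least one such junction is
      left with its EJC in place.
    """
    if t.cds_start is None:
        raise CoordinateError(f"{t.id}: cannot classify without an annotated CDS")
    junc = junctions(t)
    first_junction = junc.positions[0] if junc.positions else None
    if first_junction is None or t.cds_start <= first_junction:
        return FivePrimeClass.ATG_IN_FIRST_EXON
    utr_end = t.cds_start - 1
    if utr_end < 6:
        return FivePrimeClass.NO_UORF
    uorfs = scan_orfs(
        t,
        region=(1, utr_end),
        min_length=min_uorf_length,
        orf_region=Region.FIVE_PRIME_UTR,
    )
    if not uorfs:
        return FivePrimeClass.NO_UORF
    first_end = min(o.end for o in uorfs)
    needed = [j for j in junc if first_end < j < t.cds_start]
    if all(any(neutralizes(o, j, threshold) for o in uorfs) for j in needed):
        return FivePrimeClass.UORF_IMMUNE
    return FivePrimeClass.UORF_ELICITING


@dataclass(frozen=True)
class CensusTable:
    """Per-exon counts of annotated start-codon positions."""

    counts: dict[int, int]
    total: int

    @property
    def percentages(self) -> dict[int, float]:
        if self.total == 0:
            return {}
        return {k: 100.0 * v / self.total for k, v in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        exons = sorted(self.counts)
        return pd.DataFrame(
            {
                "exon": exons,
                "n_transcripts": [self.counts[e] for e in exons],
                "pct_of_total": [self.percentages[e] for e in exons],
            }
        )


def atg_exon_census(ts: Sequence[TranscriptModel]) -> CensusTable:
    """Count, per exon ordinal, transcripts whose annotated ATG lies there."""
    counts: dict[int, int] = {}
    for t in ts:
        if t.cds_start is None:
            raise CoordinateError(f"{t.id}: census requires an annotated CDS")
        # prefix-sum bisection for the exon ordinal
        prefix = list(itertools.accumulate(t.exon_lengths))
        ordinal = bisect_left(prefix, t.cds_start) + 1
        counts[ordinal] = counts.get(ordinal, 0) + 1
    return CensusTable(counts=counts, total=len(ts))


@dataclass
class ScreenConfig:
    """All thresholds of the screening pipeline."""

    threshold: int = DEFAULT_THRESHOLD
    strict: bool = True
    min_rescue_orf_length: int = 6
    min_uorf_length: int = DEFAULT_MIN_UORF_LENGTH
    uorf_length_strict: bool = True  # candidates must be strictly > min_uorf_length
    evalue_cutoff: float = 1.0e-6
    coverage_cutoff: float = 0.5
    positive_ratio_cutoff: float = 0.5
    align_ratio_cutoff: float = 0.8
    alpha: float = 0.05


@dataclass
class FunnelReport:
    """Per-stage counts of the screening pipeline."""

    n_input: int = 0
    n_classic_eliciting: int = 0
    n_with_rescue: int = 0
    n_rescue_orfs: int = 0
    n_atg_first_exon: int = 0
    n_no_uorf: int = 0
    n_uorf_immune: int = 0
    n_uorf_eliciting: int = 0
    n_long_uorf_candidates: int = 0
    n_kozak_positive_candidates: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": list(vars(self)), "count": list(vars(self).values())}
        )


def screen_pipeline(
    ts: Sequence[TranscriptModel],
    config: Optional[ScreenConfig] = None,
) -> tuple[pd.DataFrame, FunnelReport]:
    """Run the full architecture screen over a transcript set.

    Orchestrates the classic 3' classification, the 3'-UTR rescue
    search, the 5'-UTR classification and the long-uORF/Kozak candidate
    filters, emitting one row per transcript with all intermediate
    verdicts plus a per-stage funnel report.
    """
    cfg = config or ScreenConfig()
    funnel = FunnelReport(n_input=len(ts))
    rows: list[dict] = []
    for t in ts:
        classic = classify_classic(t, threshold=cfg.threshold, strict=cfg.strict)
        row: dict = {
            "id": t.id,
            "n_exons": t.n_exons,
            "classic_status": classic.status.value,
            "stop_to_terminal_junction": classic.stop_to_terminal_junction,
            "n_rescue_units": 0,
            "n_rescue_orfs": 0,
            "rescue_orfs": "",
            "rescued": False,
        }
        if classic.status is NmdStatus.ELICITING:
            funnel.n_classic_eliciting += 1
            units = find_rescue_units(
                t,
                threshold=cfg.threshold,
                min_orf_length=cfg.min_rescue_orf_length,
                strict=cfg.strict,
            )
            distinct = sorted(
                {(o.start, o.end) for u in units for o in u.orfs}
            )
            row["n_rescue_units"] = len(units)
            row["n_rescue_orfs"] = len(distinct)
            row["rescue_orfs"] = ";".join(f"{s}..{e}" for s, e in distinct)
            row["rescued"] = bool(units)
            if units:
                funnel.n_with_rescue += 1
                funnel.n_rescue_orfs += len(distinct)

        five = classify_five_prime(t, threshold=cfg.threshold)
        row["five_prime_class"] = five.value
        if five is FivePrimeClass.ATG_IN_FIRST_EXON:
            funnel.n_atg_first_exon += 1
        elif five is FivePrimeClass.NO_UORF:
            funnel.n_no_uorf += 1
        elif five is FivePrimeClass.UORF_IMMUNE:
            funnel.n_uorf_immune += 1
        else:
            funnel.n_uorf_eliciting += 1

        # functional-uORF candidacy: immune 5' architecture with a long uORF
        row["long_uorf"] = ""
        row["long_uorf_kozak"] = False
        if five is FivePrimeClass.UORF_IMMUNE and t.cds_start is not None:
            long_min = (
                cfg.min_uorf_length + 1
                if cfg.uorf_length_strict
                else cfg.min_uorf_length
            )
            long_uorfs = scan_orfs(
                t,
                region=(1, t.cds_start - 1),
                min_length=long_min,
                orf_region=Region.FIVE_PRIME_UTR,
            )
            if long_uorfs:
                funnel.n_long_uorf_candidates += 1
                best = max(long_uorfs, key=lambda o: (o.kozak_positive, o.length))
                row["long_uorf"] = f"{best.start}..{best.end}"
                row["long_uorf_kozak"] = best.kozak_positive
                if any(o.kozak_positive for o in long_uorfs):
                    funnel.n_kozak_positive_candidates += 1
        rows.append(row)

    columns = [
        "id",
        "n_exons",
        "classic_status",
        "stop_to_terminal_junction",
        "n_rescue_units",
        "n_rescue_orfs",
        "rescue_orfs",
        "rescued",
        "five_prime_class",
        "long_uorf",
        "long_uorf_kozak",
    ]
    table = pd.DataFrame(rows, columns=columns)
    return table, funnel
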