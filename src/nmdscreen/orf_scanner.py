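"""ATG-initiated ORF enumeration, Kozak context, and translation.

ORFs are scanned in the three reading frames 5'->3'. An ORF runs from an
ATG to the first in-frame stop codon (TAA/TAG/TGA), both inside the
requested region; the reported interval includes the stop codon.
Overlapping ORFs — nested starts in the same frame or ORFs in different
frames — are all reported. Codons containing N can neither open nor
close an ORF.

The Kozak criterion used throughout is the minimal one: a purine (A/G)
at position -3 relative to the A of the ATG.
"""

from __future__ import annotations

from typing import Optional

from Bio.Seq import Seq

from nmdscreen.transcript_model import (
    STOP_CODONS,
    CoordinateError,
    OrfCall,
    Region,
    TranscriptModel,
)


def scan_orfs(
    t: TranscriptModel,
    region: Optional[tuple[int, int]] = None,
    min_length: int = 6,
    orf_region: Region = Region.THREE_PRIME_UTR,
    annotate_kozak: bool = True,
) -> list[OrfCall]:
    """Enumerate every ATG->stop ORF fully inside ``region``.

    Parameters
    ----------
    t
        Transcript providing the spliced sequence.
    region
        1-based inclusive interval to scan; defaults to the whole
        transcript.
    min_length
        Minimal ORF length in nt, stop codon included. ORFs shorter than
        this are dropped (``>=`` comparison); 6 admits everything down to
        a single codon plus stop.
    orf_region
        Region label stamped on the returned calls.
    annotate_kozak
        Evaluate the minimal Kozak context for each start.

    Returns
    -------
    list of OrfCall
        Sorted by (start, end). Each start is paired with the FIRST
        in-frame stop at or after it inside the region, so ORFs contain
        no internal stop; nested ATGs yield their own (overlapping) calls.
    """
    lo, hi = region if region is not None else (1, len(t))
    if lo > hi:
        raise CoordinateError(f"inverted region {lo}..{hi}")
    if lo < 1 or hi > len(t):
        raise CoordinateError(f"region {lo}..{hi} outside 1..{len(t)}")

    seq = t.sequence
    calls: list[OrfCall] = []
    # first in-frame stop at/after each position, per frame, via a single
    # right-to-left sweep (linear time)
    next_stop: dict[int, dict[int, int]] = {0: {}, 1: {}, 2: {}}
    for s in range(hi - 2, lo - 1, -1):  # s is 1-based codon start
        codon = seq[s - 1 : s + 2]
        fr = (s - 1) % 3
        if codon in STOP_CODONS:
            next_stop[fr][s] = s
        else:
            next_stop[fr][s] = next_stop[fr].get(s + 3, 0)

    for s in range(lo, hi - 1):
        if seq[s - 1 : s + 2] != "ATG":
            continue
        fr = (s - 1) % 3
        stop_start = next_stop[fr].get(s + 3, 0)
        if stop_start == 0:
            continue  # open-ended: no in-region stop, not reported
        end = stop_start + 2
        length = end - s + 1
        if length < max(min_length, 6):
            continue
        koz = kozak_positive(t, s) if annotate_kozak else False
        calls.append(
            OrfCall(start=s, end=end, frame=fr, kozak_positive=koz, region=orf_region)
        )
    calls.sort(key=lambda o: (o.start, o.end))
    return calls


def kozak_positive(t: TranscriptModel, atg_start: int) -> bool:
    """Minimal Kozak test: purine at -3 relative to the A of the ATG.

    Returns ``False`` when ``atg_start < 4`` (the -3 base does not
    exist — a truncated context cannot be called positive).
    """
    if atg_start < 1 or atg_start + 2 > len(t):
        raise CoordinateError(f"ATG at {atg_start} outside transcript")
    if t.slice(atg_start, atg_start + 2) != "ATG":
        raise CoordinateError(f"no ATG at position {atg_start}")
    if atg_start < 4:
        return False
    return t.base(atg_start - 3) in ("A", "G")


def translate_orf(t: TranscriptModel, orf: OrfCall) -> str:
    """Standard-code protein of an ORF, terminal stop excluded.

    Raises
    ------
    ValueError
        If the ORF contains an internal stop codon (invariant violation).
    """
    coding = t.slice(orf.start, orf.end - 3)
    protein = str(Seq(coding).translate(table=1))
    if "*" in protein:
        raise ValueError(
            f"{t.id}: ORF {orf.start}..{orf.end} contains an internal stop"
        )
    return protein
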