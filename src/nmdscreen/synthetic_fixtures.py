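"""Deterministic generators of labeled transcripts and expression matrices.

Each architecture class the screen distinguishes can be generated with a
planted ground truth: exon lengths, ATG/stop positions and junction
distances are laid out by construction, and the random sequence fill can
never create a spurious start codon — filler never emits a G right
after an ``AT`` dinucleotide, and planted ORF interiors use A-free
codons, so the only ATG trinucleotides in a fixture are the planted
ones. Every generated transcript is re-classified before being emitted
(a self-check loop); a layout that cannot fit its requested distances
raises :class:`GenerationError` rather than emitting a mislabeled
record.

Expression fixtures emulate GINI comparisons: log-normal intensities
per probe, with the inhibited-arm mean multiplied by a fold change for
planted NMD-sensitive probes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from nmdscreen.nmd_architecture import (
    FivePrimeClass,
    classify_classic,
    classify_five_prime,
    find_rescue_units,
)
from nmdscreen.transcript_model import (
    NmdStatus,
    TranscriptModel,
    stop_junction_distance,
)

_STOPS = ("TAA", "TAG", "TGA")
# codons without A can neither be a stop nor contribute to an ATG
_SAFE_CODON_BASES = "CGT"


class GenerationError(ValueError):
    """The requested architecture cannot be planted with these parameters."""


class ArchitectureLabel(Enum):
    MONO_IMMUNE = "mono_immune"
    CLASSIC_PTC = "classic_ptc"
    BICISTRONIC_3PRIME = "bicistronic_3prime"
    STOP_NEAR_JUNCTION = "stop_near_junction"
    ATG_EXON1 = "atg_exon1"
    NO_UORF = "no_uorf"
    UORF_IMMUNE = "uorf_immune"
    UORF_ELICITING = "uorf_eliciting"
    MULTI_ORF_RESCUE = "multi_orf_rescue"


@dataclass(frozen=True)
class LabeledTranscript:
    transcript: TranscriptModel
    label: ArchitectureLabel


def _orf_text(rng: np.random.Generator, length: int) -> str:
    """ATG + A-free codons + stop, exactly ``length`` nt (multiple of 3)."""
    if length < 6 or length % 3 != 0:
        raise GenerationError(f"ORF length {length} must be >=6 and divisible by 3")
    n_mid = length // 3 - 2
    mid = "".join(
        rng.choice(list(_SAFE_CODON_BASES), size=3 * n_mid)
    )
    return "ATG" + mid + str(rng.choice(_STOPS))


def _fill_sequence(
    rng: np.random.Generator,
    total: int,
    fixed: list[tuple[int, str]],
    gc: float = 0.5,
) -> str:
    """Assemble a sequence of ``total`` nt with fixed segments planted.

    ``fixed`` holds (1-based start, text) pairs. Filler bases are drawn
    with the configured GC content, except that G is never emitted
    immediately after an ``AT`` dinucleotide — the one rule that keeps
    filler (and every filler/segment seam) free of spurious ATGs.
    """
    slots: list[Optional[str]] = [None] * total
    for start, text in fixed:
        if start < 1 or start + len(text) - 1 > total:
            raise GenerationError(f"fixed segment {start}..{start + len(text) - 1} outside 1..{total}")
        for i, ch in enumerate(text):
            if slots[start - 1 + i] is not None:
                raise GenerationError("overlapping fixed segments")
            slots[start - 1 + i] = ch
    bases = np.array(list("ACGT"))
    weights = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out: list[str] = []
    for i in range(total):
        if slots[i] is not None:
            out.append(slots[i])  # type: ignore[arg-type]
            continue
        if i >= 2 and out[i - 2] == "A" and out[i - 1] == "T":
            w = weights.copy()
            w[2] = 0.0  # no G after AT
            w = w / w.sum()
        else:
            w = weights
        out.append(str(rng.choice(bases, p=w)))
    return "".join(out)


def _frame_fit(start: int, approx_end: int, lo: int, hi: int) -> int:
    """Largest end in [lo, hi] near ``approx_end`` with length % 3 == 0."""
    end = approx_end - ((approx_end - start + 1) % 3)
    while end > hi:
        end -= 3
    if end < lo or end - start + 1 < 6:
        raise GenerationError("cannot frame-fit ORF into the requested interval")
    return end


def make_transcript(
    label: ArchitectureLabel,
    seed: int = 0,
    gc: float = 0.5,
    ident: Optional[str] = None,
) -> LabeledTranscript:
    """Generate one transcript provably belonging to ``label``.

    The same (label, seed, gc) triple always yields a byte-identical
    transcript. The emitted record is re-classified as a self-check.
    """
    key = f"{label.value}|{seed}|{gc:.6f}".encode()
    rng = np.random.default_rng(zlib.crc32(key) % 2**31)
    name = ident or f"SYN_{label.value.upper()}_{seed}"
    e = lambda lo, hi: int(rng.integers(lo, hi + 1))
    fixed: list[tuple[int, str]] = []

    if label is ArchitectureLabel.MONO_IMMUNE:
        exons = [e(400, 600)]
        cds_start = e(30, 60)
        cds_end = cds_start + 3 * e(40, 80) - 1
        fixed.append((cds_start, _orf_text(rng, cds_end - cds_start + 1)))
    elif label is ArchitectureLabel.CLASSIC_PTC:
        exons = [e(150, 250), e(150, 250), e(150, 250)]
        terminal = exons[0] + exons[1]
        cds_end = terminal - 100
        cds_start = cds_end - 3 * e(30, 45) + 1
        if cds_start < 10:
            cds_start += 3 * ((10 - cds_start) // 3 + 1)
        fixed.append((cds_start, _orf_text(rng, cds_end - cds_start + 1)))
    elif label is ArchitectureLabel.BICISTRONIC_3PRIME:
        exons = [e(150, 250), e(150, 250), e(150, 250), e(150, 250)]
        j3 = sum(exons[:3])
        cds_start = e(12, 30)
        cds_end = _frame_fit(cds_start, j3 - e(80, 120), cds_start + 60, j3 - 56)
        fixed.append((cds_start, _orf_text(rng, cds_end - cds_start + 1)))
        orf_start = cds_end + e(5, 15)
        orf_end = _frame_fit(orf_start, j3 + 30, j3 - 55, sum(exons) - 5)
        fixed.append((orf_start, _orf_text(rng, orf_end - orf_start + 1)))
    elif label is ArchitectureLabel.STOP_NEAR_JUNCTION:
        exons = [e(220, 300), e(100, 300)]
        cds_end = exons[0] - 45
        cds_start = cds_end - 3 * e(30, 50) + 1
        if cds_start < 10:
            cds_start += 3 * ((10 - cds_start) // 3 + 1)
        fixed.append((cds_start, _orf_text(rng, cds_end - cds_start + 1)))
    elif label is ArchitectureLabel.ATG_EXON1:
        exons = [e(150, 250), e(150, 250), e(150, 250)]
        j2 = exons[0] + exons[1]
        cds_start = e(12, 40)
        cds_end = _frame_fit(cds_start, j2 + 60, j2 + 10, sum(exons) - 10)
        fixed.append((cds_start, _orf_text(rng, cds_end - cds_start + 1)))
    elif label is ArchitectureLabel.NO_UORF:
        exons = [e(150, 250), e(150, 250), e(150, 250)]
        j2 = exons[0] + exons[1]
        cds_start = exons[0] + e(30, 60)
        cds_end = _frame_fit(cds_start, j2 + 60, j2 + 10, sum(exons) - 10)
        fixed.append((cds_start, _orf_text(rng, cds_end - cds_start + 1)))
    elif label is ArchitectureLabel.UORF_IMMUNE:
        exons = [e(150, 250), e(150, 250), e(150, 250), e(150, 250)]
        j2 = exons[0] + exons[1]
        j3 = j2 + exons[2]
        u_start = e(12, 25)
        u_end = _frame_fit(u_start, j2 - 20, j2 - 55, j2 - 5)
        fixed.append((u_start, _orf_text(rng, u_end - u_start + 1)))
        cds_start = j2 + e(30, min(60, exons[2] - 10))
        cds_end = _frame_fit(cds_start, j3 + 60, j3 + 10, sum(exons) - 10)
        fixed.append((cds_start, _orf_text(rng, cds_end - cds_start + 1)))
    elif label is ArchitectureLabel.UORF_ELICITING:
        exons = [e(220, 300), e(150, 250), e(150, 250)]
        j1 = exons[0]
        j2 = j1 + exons[1]
        u_start = e(12, 25)
        u_end = _frame_fit(u_start, j1 - 80, u_start + 5, j1 - 56)
        fixed.append((u_start, _orf_text(rng, u_end - u_start + 1)))
        cds_start = j2 + e(30, min(60, exons[2] - 10))
        cds_end = _frame_fit(cds_start, sum(exons) - 20, cds_start + 30, sum(exons) - 5)
        fixed.append((cds_start, _orf_text(rng, cds_end - cds_start + 1)))
    elif label is ArchitectureLabel.MULTI_ORF_RESCUE:
        exons = [e(200, 260), e(200, 260), e(200, 260), e(200, 260)]
        j2 = exons[0] + exons[1]
        j3 = j2 + exons[2]
        cds_start = e(12, 30)
        cds_end = _frame_fit(cds_start, j2 - 100, cds_start + 60, j2 - 56)
        fixed.append((cds_start, _orf_text(rng, cds_end - cds_start + 1)))
        # ORF A spans junction 2 but stops long before the window of junction 3
        a_start = cds_end + e(5, 15)
        a_end = _frame_fit(a_start, j2 + 40, j2 - 55, j3 - 60)
        fixed.append((a_start, _orf_text(rng, a_end - a_start + 1)))
        # ORF B starts strictly downstream of junction 2 and spans junction 3
        b_start = max(a_end + e(3, 10), j2 + 1)
        b_end = _frame_fit(b_start, j3 + 40, j3 - 55, sum(exons) - 5)
        fixed.append((b_start, _orf_text(rng, b_end - b_start + 1)))
    else:  # pragma: no cover
        raise GenerationError(f"unknown label {label}")

    sequence = _fill_sequence(rng, sum(exons), fixed, gc=gc)
    transcript = TranscriptModel(
        id=name,
        sequence=sequence,
        exon_lengths=tuple(exons),
        cds_start=cds_start,
        cds_end=cds_end,
        validated=True,
    )
    _self_check(transcript, label)
    return LabeledTranscript(transcript=transcript, label=label)


def _self_check(t: TranscriptModel, label: ArchitectureLabel) -> None:
    """Re-classify the emitted transcript and verify its planted label."""
    classic = classify_classic(t)
    ok = True
    if label is ArchitectureLabel.MONO_IMMUNE:
        ok = t.n_exons == 1 and classic.status is NmdStatus.IMMUNE
    elif label is ArchitectureLabel.CLASSIC_PTC:
        ok = classic.status is NmdStatus.ELICITING and not find_rescue_units(t)
    elif label is ArchitectureLabel.BICISTRONIC_3PRIME:
        units = find_rescue_units(t)
        ok = (
            classic.status is NmdStatus.ELICITING
            and len(units) > 0
            and all(len(u.orfs) == 1 for u in units)
        )
    elif label is ArchitectureLabel.STOP_NEAR_JUNCTION:
        ok = classic.status is NmdStatus.IMMUNE and stop_junction_distance(t) == 45
    elif label is ArchitectureLabel.ATG_EXON1:
        ok = (
            classic.status is NmdStatus.IMMUNE
            and classify_five_prime(t) is FivePrimeClass.ATG_IN_FIRST_EXON
        )
    elif label is ArchitectureLabel.NO_UORF:
        ok = (
            classic.status is NmdStatus.IMMUNE
            and classify_five_prime(t) is FivePrimeClass.NO_UORF
        )
    elif label is ArchitectureLabel.UORF_IMMUNE:
        ok = (
            classic.status is NmdStatus.IMMUNE
            and classify_five_prime(t) is FivePrimeClass.UORF_IMMUNE
        )
    elif label is ArchitectureLabel.UORF_ELICITING:
        ok = (
            classic.status is NmdStatus.IMMUNE
            and classify_five_prime(t) is FivePrimeClass.UORF_ELICITING
        )
    elif label is ArchitectureLabel.MULTI_ORF_RESCUE:
        units = find_rescue_units(t)
        ok = (
            classic.status is NmdStatus.ELICITING
            and len(units) > 0
            and any(len(u.orfs) >= 2 for u in units)
        )
    if not ok:
        raise GenerationError(f"{t.id}: self-check failed for label {label.value}")


def make_transcript_set(
    n_per_label: int = 100,
    seed: int = 0,
    labels: Optional[list[ArchitectureLabel]] = None,
) -> list[LabeledTranscript]:
    """A balanced labeled set, ``n_per_label`` transcripts per class."""
    chosen = labels if labels is not None else list(ArchitectureLabel)
    out: list[LabeledTranscript] = []
    for label in chosen:
        for k in range(n_per_label):
            out.append(
                make_transcript(
                    label,
                    seed=seed * 1_000_003 + k,
                    ident=f"SYN_{label.value.upper()}_{seed}_{k}",
                )
            )
    return out


def recover_label(row: pd.Series) -> ArchitectureLabel:
    """Infer the planted architecture class from one screen-pipeline row."""
    if row["n_exons"] == 1:
        return ArchitectureLabel.MONO_IMMUNE
    if row["classic_status"] == NmdStatus.ELICITING.value:
        if not row["rescued"]:
            return ArchitectureLabel.CLASSIC_PTC
        if row["n_rescue_orfs"] >= 2:
            return ArchitectureLabel.MULTI_ORF_RESCUE
        return ArchitectureLabel.BICISTRONIC_3PRIME
    if row["stop_to_terminal_junction"] == 45:
        return ArchitectureLabel.STOP_NEAR_JUNCTION
    return {
        FivePrimeClass.ATG_IN_FIRST_EXON.value: ArchitectureLabel.ATG_EXON1,
        FivePrimeClass.NO_UORF.value: ArchitectureLabel.NO_UORF,
        FivePrimeClass.UORF_IMMUNE.value: ArchitectureLabel.UORF_IMMUNE,
        FivePrimeClass.UORF_ELICITING.value: ArchitectureLabel.UORF_ELICITING,
    }[row["five_prime_class"]]


def make_expression(
    n_probes: int,
    n_sensitive: int,
    fold_change: float = 2.0,
    n_per_arm: int = 4,
    seed: int = 0,
    log_sd: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame, list[bool]]:
    """Simulate a GINI probe x sample matrix with planted sensitive probes.

    Intensities are log-normal around a per-probe baseline; planted
    NMD-sensitive probes have their inhibited-arm mean multiplied by
    ``fold_change``. Returns (matrix, sample-group sidecar, truth
    labels), all deterministic under ``seed``.
    """
    if n_per_arm < 2:
        raise GenerationError("n_per_arm must be >= 2")
    if n_sensitive > n_probes:
        raise GenerationError("n_sensitive exceeds n_probes")
    if n_sensitive > 0 and fold_change <= 1.0:
        raise GenerationError("fold_change must exceed 1 for sensitive probes")
    rng = np.random.default_rng(seed)
    sensitive = np.zeros(n_probes, dtype=bool)
    sensitive[:n_sensitive] = True
    sensitive = sensitive[rng.permutation(n_probes)]

    mu = rng.uniform(5.0, 9.0, size=n_probes)  # natural-log baseline
    control = np.exp(rng.normal(mu[:, None], log_sd, size=(n_probes, n_per_arm)))
    shift = np.where(sensitive, np.log(fold_change), 0.0)
    inhibited = np.exp(
        rng.normal((mu + shift)[:, None], log_sd, size=(n_probes, n_per_arm))
    )

    control_cols = [f"ctrl_{i + 1}" for i in range(n_per_arm)]
    inhibited_cols = [f"inhib_{i + 1}" for i in range(n_per_arm)]
    matrix = pd.DataFrame(
        np.hstack([control, inhibited]), columns=control_cols + inhibited_cols
    )
    matrix.insert(0, "probe_id", [f"P{i + 1:05d}" for i in range(n_probes)])
    matrix.insert(1, "gene_id", [f"G{i + 1:05d}" for i in range(n_probes)])
    groups = pd.DataFrame(
        {
            "sample": control_cols + inhibited_cols,
            "group": ["control"] * n_per_arm + ["inhibited"] * n_per_arm,
        }
    )
    return matrix, groups, sensitive.tolist()
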