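"""Expression-based and TIS-based validation of polycistronic candidates.

GINI (Gene Identification by NMD Inhibition) experiments compare mRNA
levels with and without an NMD inhibitor (emetine, caffeine, UPF1/Ago2
siRNA). A genuine NMD substrate accumulates when decay is blocked, so a
significant *increase* under inhibition is called NMD-sensitive; a
non-significant difference is NMD-insensitive; a significant *decrease*
contradicts the stabilization model and is flagged inconclusive.
Significance uses the two-sided unequal-variance (Welch) t-test, with
no multiple-testing correction across probes.

Translation-initiation-site (TIS) validation matches predicted rescue
ORFs against an experimentally mapped TIS table on transcript id, start
coordinate and ORF length; a transcript with several predicted rescue
ORFs of which exactly one is found is a partial match.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

DEFAULT_ALPHA = 0.05


class Direction(Enum):
    UP_ON_INHIBITION = "up"
    DOWN = "down"
    NONE = "none"


class SensitivityVerdict(Enum):
    NMD_SENSITIVE = "nmd_sensitive"
    NMD_INSENSITIVE = "nmd_insensitive"
    INCONCLUSIVE = "inconclusive"


class MatchType(Enum):
    EXACT = "exact"
    PARTIAL = "partial"
    NONE = "none"


class StatisticsError(ValueError):
    """Input does not support the requested statistical computation."""


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided p-value of the unequal-variance (Welch) t-test.

    Degrees of freedom follow Welch-Satterthwaite. Each group needs at
    least two values. When both groups have zero variance, p is 1 for
    equal means and 0 otherwise (a degenerate but decided comparison).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise StatisticsError("each group needs >= 2 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise StatisticsError("non-finite expression values")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        return 1.0 if x.mean() == y.mean() else 0.0
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


@dataclass
class ExpressionComparison:
    """Control-vs-inhibition expression values for one probe, with verdict."""

    probe_id: str
    gene_id: str
    control_values: list[float]
    inhibited_values: list[float]
    unique_gene: bool = True
    scale: str = "as-given"  # recorded, never transformed
    p_value: Optional[float] = None
    direction: Direction = Direction.NONE
    verdict: Optional[SensitivityVerdict] = None


def gini_verdict(
    comp: ExpressionComparison, alpha: float = DEFAULT_ALPHA
) -> ExpressionComparison:
    """Assign the NMD-sensitivity verdict to a probe comparison.

    NMD_SENSITIVE iff p < alpha and the inhibited-arm mean exceeds the
    control mean; NMD_INSENSITIVE iff p >= alpha; INCONCLUSIVE for a
    significant decrease. The comparison is returned with ``p_value``,
    ``direction`` and ``verdict`` filled in.
    """
    comp.p_value = welch_t_test(comp.control_values, comp.inhibited_values)
    mean_c = float(np.mean(comp.control_values))
    mean_i = float(np.mean(comp.inhibited_values))
    if mean_i > mean_c:
        comp.direction = Direction.UP_ON_INHIBITION
    elif mean_i < mean_c:
        comp.direction = Direction.DOWN
    else:
        comp.direction = Direction.NONE
    if comp.p_value >= alpha:
        comp.verdict = SensitivityVerdict.NMD_INSENSITIVE
    elif comp.direction is Direction.UP_ON_INHIBITION:
        comp.verdict = SensitivityVerdict.NMD_SENSITIVE
    else:
        comp.verdict = SensitivityVerdict.INCONCLUSIVE
    return comp


@dataclass(frozen=True)
class TisMatch:
    """Outcome of matching one predicted ORF against the TIS table."""

    transcript_id: str
    predicted_start: int
    predicted_length: int
    matched: bool
    match_type: MatchType


def match_tis(
    predictions: Sequence[tuple[str, int, int]],
    tis_table: Sequence[tuple[str, int, int]],
) -> list[TisMatch]:
    """Match predicted (transcript_id, start, length) rows to a TIS table.

    EXACT requires equality on all three fields. When a transcript has
    two or more predicted rescue ORFs and exactly one of them is found,
    every row of that transcript is labeled PARTIAL (matched is still
    per-row). Duplicate prediction keys are an input error.
    """
    if len(set(predictions)) != len(predictions):
        raise ValueError("duplicate prediction keys")
    tis = set(tis_table)
    by_transcript: dict[str, list[tuple[str, int, int]]] = {}
    for p in predictions:
        by_transcript.setdefault(p[0], []).append(p)

    results: list[TisMatch] = []
    for p in predictions:
        tid, start, length = p
        hit = p in tis
        group = by_transcript[tid]
        n_hits = sum(1 for q in group if q in tis)
        if len(group) >= 2 and n_hits >= 1 and n_hits < len(group):
            mtype = MatchType.PARTIAL
        elif hit:
            mtype = MatchType.EXACT
        else:
            mtype = MatchType.NONE
        results.append(
            TisMatch(
                transcript_id=tid,
                predicted_start=start,
                predicted_length=length,
                matched=hit,
                match_type=mtype,
            )
        )
    return results


def read_expression_matrix(
    matrix_path: Union[str, Path], groups_path: Union[str, Path]
) -> list[ExpressionComparison]:
    """Read a probe x sample TSV plus a sample-group sidecar.

    The matrix has a ``probe_id`` column, an optional ``gene_id``
    column, an optional ``unique_gene`` column (0/1), and one column per
    sample. The sidecar TSV has columns ``sample`` and ``group`` with
    group in {control, inhibited}.
    """
    groups: dict[str, str] = {}
    with Path(groups_path).open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            groups[row["sample"]] = row["group"]
    unknown = set(groups.values()) - {"control", "inhibited"}
    if unknown:
        raise ValueError(f"unknown sample groups: {sorted(unknown)}")

    comps: list[ExpressionComparison] = []
    with Path(matrix_path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        meta = {"probe_id", "gene_id", "unique_gene"}
        for row in reader:
            control = [
                float(v)
                for s, v in row.items()
                if s not in meta and groups.get(s) == "control"
            ]
            inhibited = [
                float(v)
                for s, v in row.items()
                if s not in meta and groups.get(s) == "inhibited"
            ]
            comps.append(
                ExpressionComparison(
                    probe_id=row["probe_id"],
                    gene_id=row.get("gene_id", ""),
                    control_values=control,
                    inhibited_values=inhibited,
                    unique_gene=bool(int(row.get("unique_gene", "1"))),
                )
            )
    return comps


def read_tis_table(path: Union[str, Path]) -> list[tuple[str, int, int]]:
    """Read a TIS TSV with columns transcript_id, start, length."""
    rows: list[tuple[str, int, int]] = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append((row["transcript_id"], int(row["start"]), int(row["length"])))
    return rows


def write_verdicts(
    comps: Sequence[ExpressionComparison], path: Union[str, Path]
) -> None:
    """Write probe verdicts as TSV; ambiguous probes are listed, not judged."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["probe_id", "gene_id", "p_value", "direction", "verdict", "scale"]
        )
        for c in comps:
            verdict = (
                "ambiguous_probe"
                if not c.unique_gene
                else (c.verdict.value if c.verdict else "")
            )
            writer.writerow(
                [
                    c.probe_id,
                    c.gene_id,
                    "" if c.p_value is None else f"{c.p_value:.6g}",
                    c.direction.value,
                    verdict,
                    c.scale,
                ]
            )
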