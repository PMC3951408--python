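"""Welch t-test against a hand-coded oracle; GINI verdicts; TIS matching."""

import math

import numpy as np
import pytest
from scipy import stats

from nmdscreen.expression_validation import (
    Direction,
    ExpressionComparison,
    MatchType,
    SensitivityVerdict,
    StatisticsError,
    gini_verdict,
    match_tis,
    read_expression_matrix,
    welch_t_test,
    write_verdicts,
)
from nmdscreen.synthetic_fixtures import make_expression


def welch_oracle(a, b):
    """Textbook Welch statistic and Welch-Satterthwaite df, coded from scratch."""
    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * stats.t.sf(abs(t), df)


def test_identical_groups_give_p_one():
    assert welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)
    assert welch_t_test([10.0, 10.0, 10.0], [10.0, 10.0, 10.0]) == 1.0


def test_zero_variance_unequal_means():
    assert welch_t_test([5.0, 5.0], [7.0, 7.0]) == 0.0


def test_group_size_below_two_is_an_error():
    with pytest.raises(StatisticsError):
        welch_t_test([1.0], [1.0, 2.0])


def test_welch_matches_hand_coded_formula_on_random_fixtures():
    rng = np.random.default_rng(101)
    for _ in range(100):
        na, nb = rng.integers(2, 12, size=2)
        a = rng.normal(rng.uniform(0, 10), rng.uniform(0.5, 3), size=na)
        b = rng.normal(rng.uniform(0, 10), rng.uniform(0.5, 3), size=nb)
        assert welch_t_test(a, b) == pytest.approx(welch_oracle(a, b), abs=1e-9)


def test_welch_symmetric_and_shift_invariant():
    rng = np.random.default_rng(5)
    a = rng.normal(3, 1, 6).tolist()
    b = rng.normal(4, 2, 5).tolist()
    assert welch_t_test(a, b) == pytest.approx(welch_t_test(b, a), abs=1e-12)
    shifted = welch_t_test([x + 7.5 for x in a], [x + 7.5 for x in b])
    assert welch_t_test(a, b) == pytest.approx(shifted, abs=1e-9)


def comp(control, inhibited):
    return ExpressionComparison("p1", "g1", list(control), list(inhibited))


@pytest.mark.parametrize(
    "control, inhibited, expected_verdict, expected_direction",
    [
        ([10, 11, 10, 11], [40, 41, 40, 41], SensitivityVerdict.NMD_SENSITIVE, Direction.UP_ON_INHIBITION),
        ([10, 14, 9, 12], [11, 13, 10, 12], SensitivityVerdict.NMD_INSENSITIVE, None),
        ([40, 41, 40, 41], [10, 11, 10, 11], SensitivityVerdict.INCONCLUSIVE, Direction.DOWN),
    ],
)
def test_gini_verdicts(control, inhibited, expected_verdict, expected_direction):
    c = gini_verdict(comp(control, inhibited))
    assert c.verdict is expected_verdict
    if expected_direction is not None:
        assert c.direction is expected_direction


def test_gini_verdict_respects_alpha():
    c = comp([10.0, 11.0, 10.5, 11.5], [12.0, 13.0, 12.5, 13.5])
    judged = gini_verdict(c, alpha=0.05)
    assert judged.p_value < 0.05
    relaxed = gini_verdict(comp(c.control_values, c.inhibited_values), alpha=1e-6)
    assert relaxed.verdict is SensitivityVerdict.NMD_INSENSITIVE


def test_simulated_recovery_balanced_accuracy():
    # planted 2-fold increase, n=4 per arm, 500 probes: >= 80% balanced accuracy
    matrix, groups, truth = make_expression(
        n_probes=500, n_sensitive=250, fold_change=2.0, n_per_arm=4, seed=13
    )
    tp = tn = fp = fn = 0
    for i, row in matrix.iterrows():
        c = [row[f"ctrl_{j + 1}"] for j in range(4)]
        h = [row[f"inhib_{j + 1}"] for j in range(4)]
        call = gini_verdict(comp(c, h)).verdict is SensitivityVerdict.NMD_SENSITIVE
        if truth[i]:
            tp += call
            fn += not call
        else:
            fp += call
            tn += not call
    balanced = 0.5 * (tp / (tp + fn) + tn / (tn + fp))
    assert balanced >= 0.80


@pytest.mark.parametrize(
    "predictions, tis, expected",
    [
        # exact coordinate-and-length match
        ([("LEPR-v", 74, 111)], [("LEPR-v", 74, 111)], [MatchType.EXACT]),
        # two predicted ORFs, only one verified: both rows flagged partial
        (
            [("C19", 139, 105), ("C19", 337, 42)],
            [("C19", 337, 42)],
            [MatchType.PARTIAL, MatchType.PARTIAL],
        ),
        ([("X", 1, 9)], [], [MatchType.NONE]),
        # wrong length is no match even at the right start
        ([("Y", 74, 111)], [("Y", 74, 108)], [MatchType.NONE]),
    ],
)
def test_match_tis(predictions, tis, expected):
    got = [m.match_type for m in match_tis(predictions, tis)]
    assert got == expected


def test_match_tis_rejects_duplicate_predictions():
    with pytest.raises(ValueError):
        match_tis([("A", 1, 9), ("A", 1, 9)], [])


def test_expression_matrix_roundtrip_and_ambiguous_probes(tmp_path):
    matrix, groups, _ = make_expression(
        n_probes=5, n_sensitive=2, fold_change=3.0, n_per_arm=3, seed=2
    )
    matrix["unique_gene"] = [1, 1, 0, 1, 1]
    mpath, gpath = tmp_path / "m.tsv", tmp_path / "g.tsv"
    matrix.to_csv(mpath, sep="\t", index=False)
    groups.to_csv(gpath, sep="\t", index=False)
    comps = read_expression_matrix(mpath, gpath)
    assert len(comps) == 5
    assert [c.unique_gene for c in comps] == [True, True, False, True, True]
    assert all(len(c.control_values) == 3 and len(c.inhibited_values) == 3 for c in comps)
    for c in comps:
        if c.unique_gene:
            gini_verdict(c)
    out = tmp_path / "v.tsv"
    write_verdicts(comps, out)
    lines = out.read_text().splitlines()
    assert len(lines) == 6
    assert "ambiguous_probe" in lines[3]  # excluded from judgment, still listed
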