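"""The 55-nt-rule classifiers, junction neutralization and rescue search."""

import itertools

import pytest

from nmdscreen.nmd_architecture import (
    FivePrimeClass,
    ScreenConfig,
    atg_exon_census,
    classify_classic,
    classify_five_prime,
    find_rescue_units,
    neutralizes,
    screen_pipeline,
)
from nmdscreen.orf_scanner import scan_orfs
from nmdscreen.synthetic_fixtures import (
    ArchitectureLabel,
    make_transcript,
    recover_label,
)
from nmdscreen.transcript_model import (
    CoordinateError,
    NmdStatus,
    OrfCall,
    junctions,
)
from tests.conftest import build


def _transcript_with_distance(distance):
    """Two-exon transcript whose stop sits ``distance`` nt before the junction."""
    exons = [200, 100]
    cds_end = exons[0] - distance
    cds_start = cds_end - 29  # 30-nt CDS
    return build("G" * 300, exons, cds_start=cds_start, cds_end=cds_end)


@pytest.mark.parametrize(
    "distance, expected",
    [
        (45, NmdStatus.IMMUNE),    # SNURF-like architecture
        (-30, NmdStatus.IMMUNE),   # stop inside the terminal exon
        (55, NmdStatus.IMMUNE),    # boundary: strict > leaves 55 immune
        (56, NmdStatus.ELICITING),
        (100, NmdStatus.ELICITING),
    ],
)
def test_classify_classic_threshold_boundary(distance, expected):
    t = _transcript_with_distance(distance)
    assert classify_classic(t).status is expected


def test_classify_classic_nonstrict_comparator_flips_the_boundary():
    t = _transcript_with_distance(55)
    assert classify_classic(t, strict=False).status is NmdStatus.ELICITING
    assert classify_classic(t, strict=True).status is NmdStatus.IMMUNE


def test_single_exon_transcript_is_immune():
    t = build("G" * 230, [230], cds_start=31, cds_end=60)
    v = classify_classic(t)
    assert v.status is NmdStatus.IMMUNE
    assert v.stop_to_terminal_junction is None


def test_classify_classic_requires_cds():
    with pytest.raises(CoordinateError):
        classify_classic(build("G" * 100, [50, 50]))


def test_classify_classic_monotone_in_threshold():
    # raising the threshold never converts IMMUNE into ELICITING
    for distance in range(-20, 130, 7):
        t = _transcript_with_distance(distance)
        prev_immune = False
        for threshold in range(0, 140, 5):
            immune = classify_classic(t, threshold=threshold).status is NmdStatus.IMMUNE
            assert not (prev_immune and not immune)
            prev_immune = immune


@pytest.mark.parametrize(
    "orf, junction, expected",
    [
        ((10, 201), 150, True),   # ORF spans the junction
        ((11, 100), 150, True),   # ends 50 nt upstream: inside the 55-nt window
        ((10, 90), 150, False),   # ends 60 nt upstream: outside the window
        ((160, 300), 150, False), # starts downstream of the junction: never
    ],
)
def test_neutralizes_window_arithmetic(orf, junction, expected):
    start, end = orf
    call = OrfCall(start, end, (start - 1) % 3)
    assert neutralizes(call, junction) is expected


def test_rescue_single_orf_spanning_terminal_junction(labeled_set):
    lt = make_transcript(ArchitectureLabel.BICISTRONIC_3PRIME, seed=5)
    units = find_rescue_units(lt.transcript)
    assert len(units) >= 1
    assert all(len(u.orfs) == 1 for u in units)
    required = [j for j in junctions(lt.transcript) if j > lt.transcript.cds_end]
    for u in units:
        assert tuple(required) == u.neutralized_junctions


def test_rescue_no_utr_atg_yields_no_units():
    lt = make_transcript(ArchitectureLabel.CLASSIC_PTC, seed=5)
    assert find_rescue_units(lt.transcript) == []


def test_rescue_immune_transcript_yields_empty_result_not_error():
    lt = make_transcript(ArchitectureLabel.STOP_NEAR_JUNCTION, seed=5)
    assert find_rescue_units(lt.transcript) == []


def test_two_orf_unit_matches_exhaustive_subset_search():
    lt = make_transcript(ArchitectureLabel.MULTI_ORF_RESCUE, seed=5)
    t = lt.transcript
    units = find_rescue_units(t)
    assert any(len(u.orfs) == 2 for u in units)
    # oracle: exhaustive check over all scan_orfs subsets of size <= 3
    orfs = scan_orfs(t, region=(t.cds_end + 1, len(t)), min_length=6)
    required = [j for j in junctions(t) if j > t.cds_end]
    covering = []
    for size in (1, 2, 3):
        for combo in itertools.combinations(orfs, size):
            if all(any(neutralizes(o, j) for o in combo) for j in required):
                covering.append(frozenset((o.start, o.end) for o in combo))
    minimal = [c for c in covering if not any(d < c for d in covering)]
    got = {frozenset((o.start, o.end) for o in u.orfs) for u in units}
    assert got == set(minimal)


def test_rescue_monotonicity_adding_an_orf_never_hurts():
    # planting an extra 3'-UTR ORF can only shrink the uncovered junctions
    lt = make_transcript(ArchitectureLabel.CLASSIC_PTC, seed=9)
    assert find_rescue_units(lt.transcript) == []
    lt2 = make_transcript(ArchitectureLabel.BICISTRONIC_3PRIME, seed=9)
    assert find_rescue_units(lt2.transcript) != []


@pytest.mark.parametrize(
    "label, expected",
    [
        (ArchitectureLabel.ATG_EXON1, FivePrimeClass.ATG_IN_FIRST_EXON),
        (ArchitectureLabel.NO_UORF, FivePrimeClass.NO_UORF),
        (ArchitectureLabel.UORF_IMMUNE, FivePrimeClass.UORF_IMMUNE),
        (ArchitectureLabel.UORF_ELICITING, FivePrimeClass.UORF_ELICITING),
    ],
)
def test_classify_five_prime_on_planted_architectures(label, expected):
    for seed in range(5):
        lt = make_transcript(label, seed=seed)
        assert classify_five_prime(lt.transcript) is expected


def test_five_prime_classes_partition_the_labeled_set(labeled_set):
    counts = {c: 0 for c in FivePrimeClass}
    for lt in labeled_set:
        counts[classify_five_prime(lt.transcript)] += 1
    assert sum(counts.values()) == len(labeled_set)
    assert all(v > 0 for v in counts.values())


def test_atg_exon_census_counts_and_percentages():
    ts = [
        build("G" * 60, [30, 30], cds_start=10, cds_end=21),
        build("G" * 60, [30, 30], cds_start=40, cds_end=51),
        build("G" * 90, [30, 30, 30], cds_start=70, cds_end=81),
        build("G" * 60, [60], cds_start=10, cds_end=21),
    ]
    census = atg_exon_census(ts)
    assert census.counts == {1: 2, 2: 1, 3: 1}
    assert census.total == 4
    assert census.percentages[1] == pytest.approx(50.0)
    # boundary: an ATG at the exact last base of exon 1 belongs to exon 1
    t = build("G" * 60, [10, 50], cds_start=10, cds_end=21)
    assert atg_exon_census([t]).counts == {1: 1}


def test_census_sums_to_input_size(labeled_set):
    census = atg_exon_census([lt.transcript for lt in labeled_set])
    assert sum(census.counts.values()) == census.total == len(labeled_set)


def test_screen_pipeline_recovers_planted_labels(labeled_set):
    table, funnel = screen_pipeline([lt.transcript for lt in labeled_set])
    assert funnel.n_input == len(labeled_set)
    hits = sum(
        recover_label(row) is lt.label
        for (_, row), lt in zip(table.iterrows(), labeled_set)
    )
    assert hits == len(labeled_set)
    # funnel counts equal the planted class sizes
    per_class = len(labeled_set) // len(ArchitectureLabel)
    assert funnel.n_classic_eliciting == 3 * per_class  # PTC, bicistronic, multi
    assert funnel.n_with_rescue == 2 * per_class
    assert funnel.n_uorf_immune == per_class
    assert funnel.n_uorf_eliciting == per_class


def test_screen_pipeline_empty_input():
    table, funnel = screen_pipeline([])
    assert table.empty
    assert funnel.n_input == 0
    assert funnel.n_classic_eliciting == 0
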