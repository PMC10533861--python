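"""Matching, contingency tables, sensitivity, FPs/case, FROC, tests."""

import numpy as np
import pytest
from scipy import stats as sps

import aneucad as ac
from aneucad.evaluation import (
    ContingencyTable2x2,
    evaluation_report,
    lesion_sensitivity_pct,
)
from aneucad.phantom import GroundTruthLesion
from aneucad.postprocess import ScoredCandidate
from aneucad.records import CaseCandidate, CaseRecord


def lesion(x, y, z, r=2.0, lid=0):
    return GroundTruthLesion(np.array([x, y, z], dtype=float), r, lid)


def cand(x, y, z, score=0.9):
    return ScoredCandidate(np.array([x, y, z], dtype=float), score, 1)


# --------------------------------------------------------------- matching
def test_candidate_at_lesion_center_is_tp():
    labeled, n_fn = ac.match_candidates([cand(1, 1, 1)], [lesion(1, 1, 1)], 5.0)
    assert [c.label for c in labeled] == ["TP"]
    assert n_fn == 0


def test_no_candidates_two_lesions_gives_two_fn():
    labeled, n_fn = ac.match_candidates([], [lesion(0, 0, 0), lesion(9, 9, 9, lid=1)], 5.0)
    assert labeled == [] and n_fn == 2


def test_matching_equals_all_pairs_distance_oracle():
    rng = np.random.default_rng(21)
    for _ in range(30):
        cands = [cand(*rng.uniform(0, 30, 3)) for _ in range(10)]
        lesions = [lesion(*rng.uniform(0, 30, 3), r=float(rng.uniform(1, 6)), lid=i)
                   for i in range(3)]
        hit_radius = float(rng.uniform(2, 8))
        labeled, n_fn = ac.match_candidates(cands, lesions, hit_radius)
        # oracle: exhaustive all-pairs check
        exp_labels, detected = [], set()
        for c in cands:
            hit = False
            for les in lesions:
                if np.linalg.norm(c.position - les.center) <= max(hit_radius, les.radius):
                    hit = True
                    detected.add(les.lesion_id)
            exp_labels.append("TP" if hit else "FP")
        assert [c.label for c in labeled] == exp_labels
        assert n_fn == len(lesions) - len(detected)


# ------------------------------------------------------------ contingency
def test_contingency_from_constructed_screening_records():
    """The screening-study pattern: 558/20/3777/645 positive-negative splits."""
    records = (
        [CaseRecord(f"a{i}", "definite", [CaseCandidate(0.9, "TP")]) for i in range(558)]
        + [CaseRecord(f"b{i}", "suspicion", [], n_fn=1) for i in range(20)]
        + [CaseRecord(f"c{i}", "none", [CaseCandidate(0.6, "FP")]) for i in range(3777)]
        + [CaseRecord(f"d{i}", "none", []) for i in range(645)]
    )
    table = ac.case_contingency(records)
    assert (table.a, table.b, table.c, table.d) == (558, 20, 3777, 645)
    assert table.n_cases == 5000
    assert round(ac.sensitivity_pct(table), 1) == 96.5


def test_empty_records_give_zero_table():
    table = ac.case_contingency([])
    assert (table.a, table.b, table.c, table.d) == (0, 0, 0, 0)


def test_fp_only_positive_case_counts_ai_positive():
    """A suspicion case with a single FP candidate: the candidate missed the
    lesion, but the case-level AI call is positive (a=1)."""
    rec = CaseRecord("x", "suspicion", [CaseCandidate(0.7, "FP")], n_fn=1)
    table = ac.case_contingency([rec])
    assert (table.a, table.b, table.c, table.d) == (1, 0, 0, 0)


# ------------------------------------------------------------ sensitivity
@pytest.mark.parametrize(
    "a, b, expected",
    [(558, 20, 96.5), (414, 46, 90.0), (163, 2, 98.8), (106, 6, 94.6), (7, 0, 100.0)],
)
def test_sensitivity_matches_screening_tables(a, b, expected):
    table = ContingencyTable2x2(a, b, 0, 0)
    assert round(ac.sensitivity_pct(table), 1) == expected


def test_sensitivity_undefined_without_positives():
    with pytest.raises(ZeroDivisionError):
        ac.sensitivity_pct(ContingencyTable2x2(0, 0, 5, 5))


# --------------------------------------------------------------- FPs/case
def test_fps_per_case_simple_means():
    def rec(n):
        return CaseRecord("r", "none", [CaseCandidate(0.6, "FP")] * n)

    assert ac.fps_per_case([rec(1), rec(2), rec(3)]) == 2.0
    assert ac.fps_per_case([rec(0), rec(0)]) == 0.0
    assert ac.fps_per_case([rec(0), rec(0), rec(1), rec(4), rec(5)]) == 2.0
    with pytest.raises(ValueError):
        ac.fps_per_case([])


# ------------------------------------------------------------------- FROC
def test_froc_ideal_detector_is_flat_at_100():
    records = [
        CaseRecord(f"p{i}", "definite", [CaseCandidate(0.9, "TP")]) for i in range(10)
    ]
    froc = ac.froc_curve(records, 5)
    assert len(froc.points) == 5
    for k, fpc, sens in froc.points:
        assert fpc == 0.0 and sens == 100.0


def test_froc_hand_enumerated_truncations():
    case_a = CaseRecord(
        "A", "definite", [CaseCandidate(0.9, "FP"), CaseCandidate(0.8, "TP")]
    )
    case_b = CaseRecord(
        "B", "none",
        [CaseCandidate(0.7, "FP"), CaseCandidate(0.6, "FP"), CaseCandidate(0.5, "FP")],
    )
    froc = ac.froc_curve([case_a, case_b], 3)
    assert froc.points[0] == (1, 1.0, 0.0)
    assert froc.points[2] == (3, 2.0, 100.0)


def test_froc_coordinates_non_decreasing_on_random_cohort():
    records = ac.generate_case_database(ac.CohortConfig(n_cases=300, seed=17))
    froc = ac.froc_curve(records, 5)
    assert len(froc.points) == 5
    assert all(x2 >= x1 for x1, x2 in zip(froc.fps_per_case, froc.fps_per_case[1:]))
    assert all(s2 >= s1 for s1, s2 in zip(froc.sensitivity_pct, froc.sensitivity_pct[1:]))


def test_froc_requires_scores():
    rec = CaseRecord.from_counts("x", "definite", 1, 0, 0)
    with pytest.raises(ValueError):
        ac.froc_curve([rec])


# -------------------------------------------------------------- histogram
def test_histogram_bins_and_conservation():
    def rec(n):
        return CaseRecord("r", "none", [CaseCandidate(0.6, "FP")] * n)

    hist = ac.fp_count_histogram([rec(0), rec(0), rec(2)])
    assert hist["0"] == 2 and hist["2"] == 1 and hist[">=5"] == 0
    assert ac.fp_count_histogram([]) == {"0": 0, "1": 0, "2": 0, "3": 0, "4": 0, ">=5": 0}
    records = ac.generate_case_database(ac.CohortConfig(n_cases=777, seed=1))
    assert sum(ac.fp_count_histogram(records).values()) == 777


# ------------------------------------------------------- statistical tests
def ztest_oracle(x1, n1, x2, n2):
    p1, p2 = x1 / n1, x2 / n2
    pool = (x1 + x2) / (n1 + n2)
    z = (p1 - p2) / np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    return z, 2 * sps.norm.sf(abs(z))


def ttest_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t, 2 * sps.t.sf(abs(t), n1 + n2 - 2)


def chisq_oracle(a, b, c, d, yates):
    obs = np.array([[a, b], [c, d]], float)
    n = obs.sum()
    exp = np.outer(obs.sum(1), obs.sum(0)) / n
    corr = 0.5 if yates else 0.0
    stat = (((np.abs(obs - exp) - corr).clip(min=0) ** 2) / exp).sum()
    return stat, sps.chi2.sf(stat, 1)


def test_ztest_null_case():
    res = ac.two_proportion_ztest(50, 100, 50, 100)
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_ztest_primary_tuning_comparison_significant():
    res = ac.two_proportion_ztest(558, 578, 414, 460)
    assert res.p_value < 0.01


def test_ztest_secondary_comparison_matches_closed_form():
    res = ac.two_proportion_ztest(163, 165, 106, 112)
    _, p = ztest_oracle(163, 165, 106, 112)
    assert abs(res.p_value - p) < 1e-6


def test_ztest_matches_oracle_on_random_tables():
    rng = np.random.default_rng(2)
    for _ in range(100):
        n1, n2 = rng.integers(5, 500, 2)
        x1, x2 = rng.integers(1, n1), rng.integers(1, n2)
        res = ac.two_proportion_ztest(int(x1), int(n1), int(x2), int(n2))
        z, p = ztest_oracle(x1, n1, x2, n2)
        assert abs(res.statistic - z) < 1e-6 and abs(res.p_value - p) < 1e-6


def test_ttest_trivial_and_oracle_cases():
    assert ac.fp_count_ttest([0, 0, 4], [0, 0, 4]).p_value == 1.0
    res = ac.fp_count_ttest([1, 2, 3, 4], [0, 1, 1, 2])
    t, p = ttest_oracle([1, 2, 3, 4], [0, 1, 1, 2])
    assert abs(res.statistic - t) < 1e-9 and abs(res.p_value - p) < 1e-9
    with pytest.raises(ValueError):
        ac.fp_count_ttest([1], [2, 3])


def test_ttest_matches_oracle_on_random_samples():
    rng = np.random.default_rng(3)
    for _ in range(100):
        a = rng.poisson(2.0, size=int(rng.integers(2, 50)))
        b = rng.poisson(1.0, size=int(rng.integers(2, 50)))
        if a.var() == 0 and b.var() == 0:
            continue
        res = ac.fp_count_ttest(a, b)
        t, p = ttest_oracle(a, b)
        assert abs(res.statistic - t) < 1e-6 and abs(res.p_value - p) < 1e-6


def test_chisq_independence_null():
    res = ac.chisq_2x2(ContingencyTable2x2(10, 20, 30, 60), continuity_correction=False)
    assert np.isclose(res.statistic, 0.0) and np.isclose(res.p_value, 1.0)


def test_chisq_matches_oracle_on_random_tables():
    rng = np.random.default_rng(4)
    for _ in range(100):
        a, b, c, d = rng.integers(1, 200, 4)
        for yates in (True, False):
            res = ac.chisq_2x2(ContingencyTable2x2(int(a), int(b), int(c), int(d)), yates)
            stat, p = chisq_oracle(a, b, c, d, yates)
            assert abs(res.statistic - stat) < 1e-6 and abs(res.p_value - p) < 1e-6


def test_chisq_zero_margin_rejected():
    with pytest.raises(ValueError):
        ac.chisq_2x2(ContingencyTable2x2(0, 0, 5, 5))


# ---------------------------------------------------- parameter recovery
def test_evaluation_recovers_generator_parameters():
    """Sensitivity and FPs/case estimated on a synthetic cohort lie within
    4 standard errors of the configured detection probability and FP mean."""
    n, p_det, lam = 5000, 0.9, 0.99
    records = ac.generate_case_database(
        ac.CohortConfig(n_cases=n, per_lesion_detection_prob=p_det,
                        fp_rate_per_case=lam, seed=23)
    )
    sens = lesion_sensitivity_pct(records)
    n_pos = sum(1 for r in records if r.physician_positive)
    se_sens = 100 * np.sqrt(p_det * (1 - p_det) / n_pos)
    assert abs(sens - 100 * p_det) <= 4 * se_sens
    fpc = ac.fps_per_case(records)
    assert abs(fpc - lam) <= 4 * np.sqrt(lam / n)


def test_report_is_complete_and_rounded():
    records = ac.generate_case_database(ac.CohortConfig(n_cases=400, seed=6))
    report = evaluation_report(records)
    assert report["n_cases"] == 400
    assert sum(report["contingency"].values()) == 400
    assert sum(report["fp_histogram"].values()) == 400
    assert len(report["froc"]) == 5
    assert report["sensitivity_pct"] == round(report["sensitivity_pct_raw"], 1)
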