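"""Reader-study accuracy analysis for a CAD detector.

Implements the evaluation layer of a before/after threshold-tuning study:
candidate-to-lesion matching, case-level 2x2 contingency tables
(physician call x detector call), case-level sensitivity, false positives
per case, FROC curves obtained by limiting each case's candidate output to
its top k = 1..5 by score, per-case FP-count histograms, and the three
inferential tests (two-proportion z-test for sensitivity, Student's t-test
for FPs/case, Pearson chi-square with optional Yates correction for
baseline 2x2 tables).

Positivity conventions
----------------------
* A *physician-positive* case is one read as ``suspicion`` or
  ``definite`` (a suspicion reading cannot be ruled out and counts as
  positive).
* For the contingency table, the detector call is *case-level presence*:
  a case is AI-positive when the algorithm emitted at least one candidate
  of any label.
* For FROC sensitivity, a positive case counts as detected only when at
  least one *true-positive* candidate survives the top-k truncation —
  a false positive elsewhere in the scan does not find the aneurysm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .phantom import GroundTruthLesion
from .postprocess import ScoredCandidate
from .records import CaseCandidate, CaseRecord

__all__ = [
    "ContingencyTable2x2",
    "FROCCurve",
    "TestResult",
    "match_candidates",
    "case_contingency",
    "sensitivity_pct",
    "fps_per_case",
    "lesion_sensitivity_pct",
    "froc_curve",
    "fp_count_histogram",
    "two_proportion_ztest",
    "fp_count_ttest",
    "chisq_2x2",
    "evaluation_report",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Case counts: physician call (rows) x detector call (columns).

    ``a`` physician-positive & AI-positive, ``b`` physician-positive &
    AI-negative, ``c`` physician-negative & AI-positive, ``d`` both
    negative.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("contingency counts must be non-negative integers")

    @property
    def n_cases(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class FROCCurve:
    """(candidate limit k, FPs/case, sensitivity %) triples, k ascending."""

    points: tuple[tuple[int, float, float], ...]

    def __post_init__(self) -> None:
        ks = [p[0] for p in self.points]
        if ks != sorted(set(ks)):
            raise ValueError("k values must be strictly increasing")

    @property
    def fps_per_case(self) -> list[float]:
        return [p[1] for p in self.points]

    @property
    def sensitivity_pct(self) -> list[float]:
        return [p[2] for p in self.points]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    correction: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")


def match_candidates(
    candidates: list[ScoredCandidate],
    lesions: list[GroundTruthLesion],
    hit_radius_mm: float = 5.0,
) -> tuple[list[CaseCandidate], int]:
    """Adjudicate detector outputs against ground truth.

    A candidate is a true positive iff its position lies within
    ``max(hit_radius_mm, lesion radius)`` of some lesion center; a lesion
    is detected iff at least one candidate hits it.  Returns the labeled
    candidates (original order) and the number of missed lesions (FN).
    """
    if hit_radius_mm <= 0:
        raise ValueError("hit_radius_mm must be > 0")
    labeled: list[CaseCandidate] = []
    detected = np.zeros(len(lesions), dtype=bool)
    for cand in candidates:
        hit = False
        for j, les in enumerate(lesions):
            if np.linalg.norm(cand.position - les.center) <= max(hit_radius_mm, les.radius):
                hit = True
                detected[j] = True
        labeled.append(CaseCandidate(cand.score, "TP" if hit else "FP"))
    n_fn = int(len(lesions) - detected.sum())
    return labeled, n_fn


def case_contingency(records: list[CaseRecord]) -> ContingencyTable2x2:
    """Cross-tabulate physician positivity against case-level detector output."""
    a = b = c = d = 0
    for rec in records:
        if rec.physician_positive:
            if rec.ai_positive:
                a += 1
            else:
                b += 1
        elif rec.ai_positive:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d)


def sensitivity_pct(table: ContingencyTable2x2) -> float:
    """Case-level sensitivity, percent: 100*a/(a+b).

    Display convention in reports is one decimal place; the raw value is
    returned here.
    """
    if table.a + table.b == 0:
        raise ZeroDivisionError("sensitivity undefined: no physician-positive cases")
    return 100.0 * table.a / (table.a + table.b)


def fps_per_case(records: list[CaseRecord]) -> float:
    """Total FP candidates over all cases divided by the number of cases.

    Can exceed 1.0, since the detector may emit several candidates per case.
    """
    if not records:
        raise ValueError("fps_per_case requires at least one case")
    return sum(rec.n_fp for rec in records) / len(records)


def lesion_sensitivity_pct(records: list[CaseRecord]) -> float:
    """Lesion-level sensitivity: detected lesions / all true lesions.

    Under the one-lesion-per-positive-case bookkeeping, detected = cases
    with >= 1 TP, missed = total FN count.  Secondary metric for synthetic
    experiments.
    """
    detected = sum(1 for rec in records if rec.n_tp > 0)
    missed = sum(rec.n_fn for rec in records)
    if detected + missed == 0:
        raise ZeroDivisionError("no true lesions in the record set")
    return 100.0 * detected / (detected + missed)


def _truncate(rec: CaseRecord, k: int) -> CaseRecord:
    # top-k by score; deterministic tie-break on (score, TP-before-FP, index)
    order = sorted(
        range(len(rec.candidates)),
        key=lambda i: (-rec.candidates[i].score, rec.candidates[i].label != "TP", i),
    )[:k]
    kept = [rec.candidates[i] for i in sorted(order)]
    n_true = rec.n_tp + rec.n_fn  # lesions are conserved under truncation
    n_tp_kept = sum(1 for c in kept if c.label == "TP")
    return CaseRecord(rec.case_id, rec.physician_label, kept, n_true - n_tp_kept)


def froc_curve(records: list[CaseRecord], k_max: int = 5) -> FROCCurve:
    """FROC by candidate limiting: for each k = 1..k_max truncate every
    case's candidates to its top k by score, then recompute FPs/case and
    the (TP-based) case sensitivity.  Top-k lists are nested in k, so both
    coordinates are non-decreasing.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    for rec in records:
        if not rec.has_scores():
            raise ValueError(
                f"case {rec.case_id}: candidates need scores for top-k truncation"
            )
    points = []
    for k in range(1, k_max + 1):
        truncated = [_truncate(rec, k) for rec in records]
        positives = [rec for rec in truncated if rec.physician_positive]
        n_det = sum(1 for rec in positives if rec.n_tp > 0)
        sens = 100.0 * n_det / len(positives) if positives else float("nan")
        points.append((k, fps_per_case(truncated), sens))
    return FROCCurve(tuple(points))


def fp_count_histogram(records: list[CaseRecord], top_bin: int = 5) -> dict[str, int]:
    """Distribution of cases over per-case FP counts: bins 0..top_bin-1 and
    an overflow bin ``">=top_bin"``.  Bin totals always sum to the case count."""
    bins = {str(i): 0 for i in range(top_bin)}
    bins[f">={top_bin}"] = 0
    for rec in records:
        n = rec.n_fp
        key = str(n) if n < top_bin else f">={top_bin}"
        bins[key] += 1
    return bins


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Two-sided two-proportion z-test with pooled variance."""
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("trial counts must be positive")
        if not 0 <= x <= n:
            raise ValueError("successes must lie in [0, n]")
    if x1 * n2 == x2 * n1:  # identical proportions -> exact null
        return TestResult(0.0, 1.0, "two-proportion z-test (pooled)")
    stat, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
    return TestResult(float(stat), float(p), "two-proportion z-test (pooled)")


def fp_count_ttest(counts_before, counts_after) -> TestResult:
    """Two-sample Student's t-test (pooled variance, two-sided) on per-case
    FP counts."""
    before = np.asarray(counts_before, dtype=float)
    after = np.asarray(counts_after, dtype=float)
    if before.size < 2 or after.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    stat, p = stats.ttest_ind(before, after, equal_var=True)
    if np.isnan(p):  # zero pooled variance with equal means
        stat, p = 0.0, 1.0
    return TestResult(float(stat), float(p), "Student's t-test (pooled)")


def chisq_2x2(table: ContingencyTable2x2, continuity_correction: bool = True) -> TestResult:
    """Pearson chi-square on a 2x2 table, optional Yates continuity
    correction.  Requires all expected counts positive (no zero margins)."""
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: zero margin in the 2x2 table")
    res = stats.chi2_contingency(arr, correction=continuity_correction)
    return TestResult(
        float(res[0]), float(res[1]), "Pearson chi-square", continuity_correction
    )


def evaluation_report(
    records: list[CaseRecord], k_max: int = 5, histogram_top_bin: int = 5
) -> dict:
    """Full accuracy report for one record set (JSON-serializable dict).

    Percentages are displayed to one decimal, FPs/case to two, p-values to
    three, matching the conventions of screening-accuracy tables; raw
    values are included alongside.
    """
    table = case_contingency(records)
    sens = sensitivity_pct(table)
    fpc = fps_per_case(records)
    report = {
        "n_cases": len(records),
        "contingency": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
        "sensitivity_pct": round(sens, 1),
        "sensitivity_pct_raw": sens,
        "fps_per_case": round(fpc, 2),
        "fps_per_case_raw": fpc,
        "fp_histogram": fp_count_histogram(records, histogram_top_bin),
    }
    if all(rec.has_scores() for rec in records):
        froc = froc_curve(records, k_max)
        report["froc"] = [
            {"k": k, "fps_per_case": round(f, 2), "sensitivity_pct": round(s, 1)}
            for k, f, s in froc.points
        ]
    return report
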