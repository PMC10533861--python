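"""Published accuracy counts of the threshold-tuning reader study.

These are the printed case counts of the large screening study whose
evaluation methodology this package reimplements: ~10,000 consecutive
brain-screening examinations, read before and after the detector's score
cutoff was raised from 0.5 to 0.8.  The counts are inputs, not results:
every statistic derived from them (sensitivity, proportions, chi-square
and z-test p-values) is recomputed by this package's evaluation code at
run time, never hard-coded.

Primary analysis: all cases (5000 before / 5000 after tuning).
Secondary analysis: the subset with per-candidate feedback labels
(1359 before / 859 after).
"""

from __future__ import annotations

from .evaluation import ContingencyTable2x2

__all__ = [
    "PRIMARY_BEFORE",
    "PRIMARY_AFTER",
    "SECONDARY_BEFORE",
    "SECONDARY_AFTER",
    "PRIMARY_CATEGORY_COUNTS",
    "SEX_TABLE_PRIMARY",
    "SEX_TABLE_SECONDARY",
    "REPORTED",
]

# physician call (positive = suspicion or definite) x detector call, per period
PRIMARY_BEFORE = ContingencyTable2x2(a=558, b=20, c=3777, d=645)
PRIMARY_AFTER = ContingencyTable2x2(a=414, b=46, c=2617, d=1923)
SECONDARY_BEFORE = ContingencyTable2x2(a=163, b=2, c=1064, d=130)
SECONDARY_AFTER = ContingencyTable2x2(a=106, b=6, c=480, d=267)

# three-category physician diagnosis counts per 5000-case period
PRIMARY_CATEGORY_COUNTS = {
    "before": {"none": 4422, "suspicion": 478, "definite": 100},
    "after": {"none": 4540, "suspicion": 360, "definite": 100},
}

# female counts for the baseline-characteristics sex comparison:
# (female_before, n_before, female_after, n_after)
SEX_TABLE_PRIMARY = (2153, 5000, 2192, 5000)
SEX_TABLE_SECONDARY = (592, 1359, 423, 859)

# the study's printed summary statistics, for cross-checking recomputations
REPORTED = {
    "sensitivity_primary_before_pct": 96.5,
    "sensitivity_primary_after_pct": 90.0,
    "sensitivity_secondary_before_pct": 98.8,
    "sensitivity_secondary_after_pct": 94.6,
    "fps_per_case_primary_before": 2.06,
    "fps_per_case_primary_after": 0.99,
    "fps_per_case_secondary_before": 1.99,
    "fps_per_case_secondary_after": 1.03,
    "negative_rate_after_pct": 90.8,
    "sex_p_primary": 0.443,
    "sex_p_secondary": 0.009,
}
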