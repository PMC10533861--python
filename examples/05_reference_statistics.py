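"""Recompute the published screening-study statistics from their counts.

The package embeds the printed case counts of the tuning study it
reimplements (primary analysis: 5000 cases before / 5000 after raising
the score cutoff from 0.5 to 0.8; secondary analysis: the 2218-case
feedback subset).  Everything printed below — sensitivities, the
negative-case proportion, chi-square and z-test p-values — is computed
by the evaluation code from those counts at run time; matching the
published one-decimal values verifies the statistics layer end to end.

Equivalent CLI: ``aneucad reproduce-study``.
"""

import aneucad as ac
from aneucad import reference_tables as ref
from aneucad.evaluation import ContingencyTable2x2

print("case-level sensitivity (percent):")
for name, table in [
    ("primary before", ref.PRIMARY_BEFORE), ("primary after", ref.PRIMARY_AFTER),
    ("secondary before", ref.SECONDARY_BEFORE), ("secondary after", ref.SECONDARY_AFTER),
]:
    print(f"  {name:17s} a={table.a:4d} b={table.b:3d} -> "
          f"{ac.sensitivity_pct(table):.1f}%")

counts = ref.PRIMARY_CATEGORY_COUNTS["after"]
print(f"\nnegative-case rate after tuning: "
      f"{100 * counts['none'] / sum(counts.values()):.1f}%")

f1, n1, f2, n2 = ref.SEX_TABLE_PRIMARY
res = ac.chisq_2x2(ContingencyTable2x2(f1, n1 - f1, f2, n2 - f2), continuity_correction=True)
print(f"sex chi-square (primary, Yates-corrected): p = {res.p_value:.3f}")
f1, n1, f2, n2 = ref.SEX_TABLE_SECONDARY
res = ac.chisq_2x2(ContingencyTable2x2(f1, n1 - f1, f2, n2 - f2), continuity_correction=False)
print(f"sex chi-square (secondary, uncorrected):   p = {res.p_value:.3f}")

z = ac.two_proportion_ztest(558, 578, 414, 460)
print(f"sensitivity z-test (primary):   z = {z.statistic:.2f}, p = {z.p_value:.2g}")
z = ac.two_proportion_ztest(163, 165, 106, 112)
print(f"sensitivity z-test (secondary): z = {z.statistic:.2f}, p = {z.p_value:.3f}")
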