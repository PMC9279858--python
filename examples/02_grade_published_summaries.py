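"""Recompute FPRP and credibility for the packaged published summary rows.

The packaged table holds 29 significant TERT-CLPTM1L association summaries
(variant, disease, group, OR with 95% CI, I², Venice letters, printed FPRP
and credibility label).  This script recomputes FPRP from each printed
OR/CI pair and rebuilds the strong/moderate/weak calls from the Venice
letters plus the printed FPRP.
"""

from collections import Counter

from credmeta import grade_summary_table, significant_associations

table = significant_associations()
graded = grade_summary_table(table, prior=0.05, or0=1.5, use_printed_fprp=True)

print("recomputed vs printed FPRP (consistent-CI rows):")
for _, row in graded.head(6).iterrows():
    mark = "" if row.ci_consistent else "  [CI inconsistent -> excluded]"
    print(
        f"  {row.variant_id:<10} {row.disease:<28} computed={row.fprp_computed:.3f}"
        f" printed={row.fprp}{mark}"
    )

print()
print("base Venice levels:   ", dict(Counter(graded.base_level)))
print("final (with FPRP):    ", dict(Counter(graded.final_level)))
match = (graded.final_level.str.capitalize() == graded.credibility).all()
print("row-by-row label match:", bool(match))
print()
print(
    "Base levels follow the Venice letters (strong = AAA, weak = any C); the "
    "FPRP moves a call one level up below 0.05 and one level down at 0.20."
)
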