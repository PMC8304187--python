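"""The 0-4 tumor+host prognostic score and its stratification.

Tumor factors: TLG > 41.40 g and first-order entropy > 3.40 (1 point each).
Host factor: BM SUV > 1.53 (2 points). Totals pool into prognostic groups
0-2, 3 and 4.
"""

from petscore import (
    CohortSpec,
    assign_score,
    default_rule,
    evaluate_stratification,
    generate_cohort,
)

rule = default_rule()

# score single patients
for tlg, ent, bm in [(10.0, 3.0, 1.2), (55.54, 3.0, 1.74), (100.0, 4.0, 2.0)]:
    s = assign_score(tlg, ent, bm, rule)
    print(f"TLG {tlg:6.2f}, entropy {ent:.2f}, BM SUV {bm:.2f} -> "
          f"points {s.tlg_points}+{s.entropy_points}+{s.bm_points} = "
          f"{s.total} (group {s.group})")

# stratify a planted cohort
cohort = generate_cohort(CohortSpec(n=2000, baseline_hazard=0.01, seed=14))
report = evaluate_stratification(cohort, rule)
print("\nper-group survival:")
cols = ["n", "events", "median", "hazard_ratio", "hr_ci_lower", "hr_ci_upper"]
print(report.group_summary[cols].round(2).to_string())
print(f"\nC-index of the score: {report.c_index:.3f}")
print("subgroup splits:", ", ".join(report.subgroups))
# Hazard ratios rise monotonically across groups because all three factors
# carry positive planted effects; the reference group 0-2 has HR 1 by
# construction.
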