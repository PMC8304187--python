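"""Cutpoint selection and survival modelling on a synthetic cohort.

Generates a 400-patient cohort with a planted hazard step at BM SUV 1.53,
recovers the cutpoint by the maximally selected chi-square test, fits an
age/sex-adjusted Cox model for the dichotomized marker and summarizes
survival with Kaplan-Meier.
"""

import numpy as np

from petscore import CohortSpec, cox_fit, generate_cohort, km_estimate, maxstat_cutoff

spec = CohortSpec(
    n=400,
    log_hr_bm_suv=np.log(3.0),  # planted: HR 3 for BM SUV > 1.53
    log_hr_tlg=0.0, log_hr_entropy=0.0, log_hr_age=0.0, log_hr_stage=0.0,
    baseline_hazard=0.05, censoring_rate=0.012, seed=1,
)
cohort = generate_cohort(spec)
print(f"cohort: n={len(cohort)}, events={int(cohort.event.sum())}")

cut = maxstat_cutoff(cohort.bm_suv, cohort.time_months, cohort.event, variable="bm_suv")
print(f"maxstat cutpoint  : {cut.cutoff:.3f} (planted 1.53), "
      f"chi2={cut.chi2:.1f}, corrected p={cut.p_value_corrected:.2e}")

cohort["bm_high"] = (cohort.bm_suv > cut.cutoff).astype(float)
fit = cox_fit(cohort, ["bm_high"], adjust=["age", "sex"])
row = fit.summary.loc["bm_high"]
print(f"adjusted Cox HR   : {row.hazard_ratio:.2f} "
      f"(95% CI {row.ci_lower:.2f}-{row.ci_upper:.2f}), C-index {fit.c_index:.3f}")

for label, grp in (("low", cohort.bm_high == 0), ("high", cohort.bm_high == 1)):
    km = km_estimate(cohort.time_months[grp], cohort.event[grp], horizon=12)
    print(f"BM {label:4s}: median OS {km.median:6.1f} months "
          f"(95% CI {km.median_ci[0]:.1f}-{km.median_ci[1]:.1f}), "
          f"12-month OS {km.horizon_survival:.1%}")
# The high-marrow-uptake group should show the planted ~3-fold hazard and a
# correspondingly shorter median survival.
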