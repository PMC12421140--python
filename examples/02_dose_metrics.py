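"""DVH metrics and schedule constraint checks for one synthetic plan.

D95 ~ prescription and HI ~ 0 indicate good target coverage and
homogeneity; the constraint report compares OAR doses against the
schedule's limits (e.g. bladder Dmean < 40 Gy for 50 Gy/25 F).
"""

import rtplaneval as rp
from rtplaneval.cohort import generate_case

case = generate_case(rp.CohortConfig(n_cases=4, seed=3), 1)  # a 50 Gy/25F case
metrics = rp.summarize_case_dose(case, "auto")

print(f"prescription: {case.prescription.label}")
for name in rp.DoseMetrics.PTV_METRICS:
    unit = "" if name in ("hi", "ci") else " Gy"
    print(f"  PTV {name:6s} {getattr(metrics, name):7.3f}{unit}")
for name in rp.DoseMetrics.OAR_METRICS:
    print(f"  {name:22s} {getattr(metrics, name):7.3f} Gy")

report = rp.check_constraints(metrics, case.prescription)
print(f"\nconstraints ({report.prescription_label}): "
      f"{'PASS' if report.passed else 'FAIL'}")
for key, c in report.checks.items():
    print(f"  {key:22s} {c['value_gy']:6.2f} Gy < {c['limit_gy']:5.1f} Gy "
          f"(margin {c['margin_gy']:+.2f})  {'ok' if c['passed'] else 'VIOLATED'}")
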