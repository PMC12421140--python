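"""Generate a small synthetic cohort and score contour agreement.

Each case pairs an automated structure set with a physician-style edited
("manual") one; DSC/JI near 1 and HD/MDA near 0 mean close agreement.
Scenario cases (SI truncation, lateral asymmetry) show larger deviations.
"""

import rtplaneval as rp

config = rp.CohortConfig(n_cases=8, seed=7)
cases = rp.generate_cohort(config)

print(f"{'case':8s} {'rx':9s} {'scenario':13s} {'DSC':>6s} {'JI':>6s} "
      f"{'HD mm':>7s} {'MDA mm':>7s} {'Vauto cc':>9s} {'Vman cc':>8s}")
for case in cases:
    g = rp.summarize_case_geometry(case)
    print(f"{case.case_id:8s} {case.prescription.label:9s} {case.scenario:13s} "
          f"{g.dsc:6.3f} {g.ji:6.3f} {g.hd_mm:7.2f} {g.mda_mm:7.2f} "
          f"{g.vol_auto_cc:9.1f} {g.vol_manual_cc:8.1f}")

print("\nManual volumes sit below automated ones: the edit model is "
      "contraction-biased, as clinicians' edits are.")
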