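"""Detect that digestion erodes otolith length faster than sulcus/cauda.

Fits pairwise baseline regressions on pristine reference otoliths, measures
how eroded prey otoliths deviate from them, and compares fish sizes
estimated from the three features within the same otoliths.
"""

import otodiet as od
from otodiet.size_models import Form, Predictor
from otodiet.types import GradeCategory, Species

cfgs = od.default_species_configs()
reference, _ = od.simulate_reference(
    {Species.WEAKFISH: cfgs[Species.WEAKFISH]}, n_per_species=150, seed=31)
stomachs, _ = od.simulate_stomachs(od.simulate_strandings(220, seed=32), seed=32)
prey = [o for s in stomachs for o in s.otoliths]

baselines = od.baseline_regressions(reference, Species.WEAKFISH)
reports = od.deviation_assessment(baselines, prey, Species.WEAKFISH,
                                  b=1000, seed=32)
print("deviation of prey otoliths from reference baselines")
print("(y observed minus y predicted from x; negative = y eroded more):")
for r in reports:
    if r.insufficient:
        continue
    print(f"  {r.pair.y_predictor.value} ~ {r.pair.x_predictor.value} "
          f"grade {r.grade_category.value}: mean {r.mean_deviation:+.3f} mm "
          f"(95% CI {r.ci_low:+.3f} to {r.ci_high:+.3f}, n = {r.n})")

models = {p: od.fit_model(reference, "weakfish", p, "FTL", Form.GOMPERTZ)
          for p in Predictor}
pc = od.predictor_comparison(models, prey, Species.WEAKFISH, b=2000, seed=32)
print("\nmean estimated fish length (mm) per predictor, by grade category:")
for cat, t in pc.per_category.items():
    means = ", ".join(f"{k}: {v:.1f}" for k, v in t.means.items())
    print(f"  grade {cat.value}: {means}")
    print(f"    CL-based exceeds OL-based by "
          f"{pc.percent_diff_cl_vs_ol[cat]:+.1f}% "
          f"(Holm-adjusted p for OL vs CL = "
          f"{t.pairwise_p_holm[('OL', 'CL')]:.4f})")
print("-> cauda length, protected inside the otolith margin, preserves the")
print("   original fish size best; the gap widens with erosion grade.")
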