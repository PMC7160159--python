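"""Reconstruct consumed biomass under the three scaling scenarios.

Builds a small synthetic stranding study, estimates per-otolith fish
weights, runs Standard / Iterative / Inclusive reconstructions and tests
the paired scenario differences.
"""

import otodiet as od
from otodiet.size_models import Form, Predictor, Response

reference, _ = od.simulate_reference(seed=21)
stomachs, truth = od.simulate_stomachs(od.simulate_strandings(60, seed=42),
                                       seed=42)

# weight models fitted on the reference collection, AIC-selected form
models = []
for sp in (od.Species.CROAKER, od.Species.SPOT, od.Species.SPOTTED_SEATROUT,
           od.Species.WEAKFISH):
    fits, table = {}, {}
    for p in Predictor:
        table[p] = {}
        for f in Form:
            m = od.fit_model(reference, sp, p, Response.FW, f)
            fits[(p, f)] = m
            table[p][f] = m.aic
    sel = od.select_model(sp, Response.FW, table)
    models += [fits[(p, sel.chosen[p])] for p in Predictor]

od.restrict_to_counted_side(stomachs)      # count fish via the higher-count side
od.estimate_weights(stomachs, models)      # croaker via SL, others via CL

results = od.run_scenarios(stomachs)
print("total reconstructed biomass (kg) by scenario:")
for sc, rs in results.items():
    print(f"  {sc.value:9s}: {sum(r.biomass_g for r in rs) / 1000:8.1f}")
print(f"  (true consumed biomass in the simulation: "
      f"{truth['fw_g'].sum() / 1000:8.1f})")

levels = [r.fallback_level_used.value for r in results[od.Scenario.ITERATIVE]]
print("\niterative fallback levels used (stomach -> month -> season -> study):")
print("  " + ", ".join(f"{lv}: {levels.count(lv)}" for lv in
                       ("none", "stomach", "month", "season", "study")))

comparison = od.compare_scenarios(results, b=2000, seed=42)
print("\npaired scenario contrasts per species (Holm-adjusted p):")
for sp, t in comparison.items():
    contrasts = ", ".join(f"{a} vs {b}: {p:.3f}"
                          for (a, b), p in t.pairwise_p_holm.items())
    print(f"  {sp.value}: {contrasts}")
print("-> reconstructions cover only fish that left a recoverable otolith,")
print("   so all scenarios sit below the true consumed biomass when side")
print("   loss and complete digestion destroy otoliths; the Inclusive")
print("   scenario drops further once eroded otoliths shrink appreciably.")
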