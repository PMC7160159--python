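"""Discriminate spotted seatrout from weakfish with the CL:SL sulcus ratio.

Learns a single-split partition rule from a synthetic reference collection
whose ratio distributions straddle the published 0.49-0.50 band, classifies
a few probe ratios, and apportions a batch of ambiguous-band otoliths.
"""

import otodiet as od

# reference collection for the two Cynoscion species only
cfgs = od.default_species_configs()
sub = {sp: cfgs[sp] for sp in (od.Species.SPOTTED_SEATROUT, od.Species.WEAKFISH)}
reference, _ = od.simulate_reference(sub, n_per_species=110, seed=11)

rule = od.learn_split(reference, folds=10, seed=11)
print(f"learned cut-points: [{rule.cut_low:.2f}, {rule.cut_high:.2f}] "
      f"(training accuracy {rule.accuracy:.3f}, CV pseudo-R2 {rule.cv_r2:.3f})")
print("-> ratios below the band are spotted seatrout, above are weakfish;")
print("   the closed band in between is ambiguous and apportioned by probability.")

for ratio in (0.45, 0.495, 0.60):
    res = od.classify_otolith(ratio, rule)
    label = res.assigned_species.value if res.assigned_species else "ambiguous"
    print(f"CL:SL = {ratio:.3f} -> {label} (p = {res.probability:.3f})")

# the published rule with its band probabilities, applied to 21 band otoliths
counts = od.apportion_ambiguous(21, od.paper_rule())
print("apportioning 21 band otoliths with the published probabilities:",
      {sp.value: n for sp, n in counts.items()})
print("-> expected counts n*p, largest-remainder rounded to whole fish.")
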