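"""Would scouting a single quadrant give the right treatment decision?

Classifies quadrant- and field-scale density estimates against the sweep-net
economic threshold (8 adults+nymphs per 100 sweeps) and quantifies how often
a single quadrant disagrees with the whole-field call.
"""

import lygusscout as ls

units = ls.generate_hierarchical_counts(ls.HierarchySpec(seed=21), "sweep")
summary = ls.agreement_analysis(units, threshold=8.0)

print(f"{summary.n_quadrants} quadrants across "
      f"{summary.n_quadrants // 4} fields, threshold {summary.threshold} "
      "per 100 sweeps")
print(f"below threshold at both scales: {summary.pct_below_both:.1f}%")
print(f"above threshold at both scales: {summary.pct_above_both:.1f}%")
print(f"quadrant disagrees with field:  {summary.pct_disagree:.1f}%")
print(f"chi-square independence test:   chi2 = {summary.chi2:.1f}, "
      f"p = {summary.p_value:.2g}")
print(f"single-quadrant inadequacy:     "
      f"{summary.p_single_quadrant_inadequate:.1f}%")
print("The last number is the chance that, in a field at or above "
      "threshold, a lone quadrant sample would read below threshold and "
      "miss the treatment decision.")
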