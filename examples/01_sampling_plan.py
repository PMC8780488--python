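"""Fixed-precision sampling plan for sweep-net scouting.

Builds a pool of 100-sweep sampling-unit counts matched to the regional
survey's moments (mean 2.9, SD 4.4 tarnished plant bugs per unit), fits
Taylor's power law per field, derives Green's fixed-precision sample size
and stop line at D = 0.25, and validates the plan by sequential resampling.
"""

import numpy as np

import lygusscout as ls

# generating variance-mean law calibrated so that per-field refits with only
# four units per field are centred on the nominal (a, b)
cal = ls.calibrate_taylor_generator(2.9, 4.4, 0.95, 1.11,
                                    n_groups=94, units_per_group=4, seed=0)
spec = ls.taylor_pool_spec(grand_mean=2.9, unit_sd=4.4, taylor_a=cal.a_gen,
                           taylor_b=cal.b_gen, n_fields=94, seed=1)
units = ls.generate_hierarchical_counts(spec, method="sweep")
print(f"simulated {len(units)} sweep-net units, "
      f"mean {units.total.mean():.2f}, SD {units.total.std():.2f}")

fit = ls.fit_taylor(units)
print(f"Taylor fit: a = {fit.a:.2f} (95% CI {fit.ci_a[0]:.2f}-{fit.ci_a[1]:.2f}), "
      f"b = {fit.b:.2f}, R^2 = {fit.r2:.2f} over {fit.n_groups} fields")
print("b > 1 indicates aggregated (patchy) spatial distribution.")

m = units.total.mean()
n_green = ls.green_sample_size(fit.a, fit.b, m, D=0.25)
print(f"Green plug-in sample size at the pooled mean: {n_green:.1f} units "
      f"(ceil -> {int(np.ceil(n_green))}) for 25% relative precision")

table = ls.stop_line(fit.a, fit.b, D=0.25, n_max=16)
print("stop line (stop once the cumulative count reaches T_n):")
print(table.iloc[[0, 3, 7, 15]].to_string(index=False))

rvsp = ls.resample_validation(units.total.to_numpy(), fit.a, fit.b,
                              D=0.25, n_sim=500, seed=2)
print(f"resampling validation: Navg = {rvsp.navg:.1f} +- {rvsp.nsd:.1f} SD, "
      f"range {rvsp.nmin}-{rvsp.nmax} units")
print("Navg exceeds the plug-in N because sequential stopping reacts to "
      "sampling noise in the running mean.")
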