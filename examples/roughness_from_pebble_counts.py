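"""Pebble counts -> weight fractions -> d50/d90 -> Manning roughness.

Builds a small synthetic pebble-count table, converts number counts to
weight fractions, extracts characteristic percentiles and evaluates the
six empirical Manning formulas plus their average.
"""

from ripacal.sediment import (
    GrainCounts,
    fehr_weight_fractions,
    manning_estimates,
    percentile,
)
from ripacal.synthetic import SyntheticSiteConfig, make_grain_counts

counts = make_grain_counts(SyntheticSiteConfig(n_grains=520, master_seed=0), 3)
print("size classes (mm):", [round(float(d), 1) for d in counts.d_mm])
print("counts:           ", [int(c) for c in counts.counts])

dist = fehr_weight_fractions(counts)
d50, d90 = percentile(dist, 0.5), percentile(dist, 0.9)
print(f"\nd50 = {d50:.1f} mm, d90 = {d90:.1f} mm "
      "(weight percentiles of the converted distribution)")

estimates, average = manning_estimates(d50, d90)
for e in estimates:
    print(f"  {e.formula:>14s}: n = {e.n_m_rounded}")
print(f"\naverage Manning n = {average:.4f} s m^-1/3 — the bare-bed "
      "roughness a hydrodynamic model would use for this reach")
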