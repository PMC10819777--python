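"""Phylogeny-aware metrics gain statistical power on matched designs.

Two sample groups share every phylogeny-blind property — 18 species per
sample, identical log-normal abundance spread (sigma 2) — and differ only
in taxonomy: LD-18 draws its species from 2 genera, HD-18 from 18. A
metric that cannot see the tree (Shannon, Bray-Curtis) sees two
identical designs; Faith's PD and weighted UniFrac separate them.
"""

import taxdiv as td
from taxdiv.synth import LdHdDesign

counts, labels, tree, tax = td.simulate_ld_hd(LdHdDesign(seed=1))
print(f"counts: {counts.shape[0]} species x {counts.shape[1]} samples "
      f"({labels.count('LD')} LD + {labels.count('HD')} HD)")

comparisons = td.diversity_power_comparison(counts, labels, tree)
print(f"\n{'metric':>12} {'type':>12} {'U':>10} {'raw p':>12} {'BH-adj p':>12}")
kinds = {"shannon": "alpha", "pd": "alpha", "braycurtis": "beta",
         "wunifrac": "beta"}
for name, comp in comparisons.items():
    print(f"{name:>12} {kinds[name]:>12} {comp.u_statistic:>10.1f} "
          f"{comp.p_value:>12.3g} {comp.p_adjusted:>12.3g}")

# Shannon cannot tell the groups apart (adjusted p well above 0.05) while
# Faith's PD separates them almost perfectly; weighted UniFrac likewise
# dwarfs Bray-Curtis. Alpha metrics run on raw counts over 50 samples per
# group; beta metrics on median-of-ratios-normalized counts over the 1225
# within-group sample pairs per group (pairs share samples, so the beta
# p-values are approximate).
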