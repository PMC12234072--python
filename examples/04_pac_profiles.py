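"""Generate per-bird PAC concentration tables and compare site exposure
signatures.

Each site profile fixes the mean LMW:HMW ratio (petrogenic sources are
LMW-dominated; natural seeps HMW-dominated) and the mean summed USEPA16
priority PACs. The comparison mirrors the study design: Kruskal-Wallis
across exposed sites, then pairwise Wilcoxon with BH correction.
"""

from pacmeth import (
    default_site_profiles,
    generate_pac_table,
    kruskal_wallis,
    lmw_hmw_ratio,
    pairwise_wilcoxon_bh,
    summarize_pac,
)

table = generate_pac_table(default_site_profiles(), seed=0)

print("site mean LMW:HMW ratios (targets 3.66 / 4.99 / 1.81 / 0.63):")
groups = {}
for site in ("REFERENCE", "SPILL", "SHIP", "SEEP"):
    mean_ratio, per_bird = lmw_hmw_ratio(table, site)
    groups[site] = per_bird.to_numpy()
    print(f"  {site:10s} {mean_ratio:.2f}  (n = {len(per_bird)})")

exposed = {s: groups[s] for s in ("SPILL", "SHIP", "SEEP")}
h, p = kruskal_wallis(list(exposed.values()))
print(f"Kruskal-Wallis across exposed sites: H = {h:.1f}, p = {p:.2e}")
print("pairwise Wilcoxon (BH-adjusted):")
print(pairwise_wilcoxon_bh(exposed).round(4))

print("\nREFERENCE class summary (ng/g):")
print(summarize_pac(table, "REFERENCE").round(2))
# SEEP should separate sharply from SPILL and SHIP (p < 0.001) while
# SPILL vs SHIP is typically non-significant, matching the exposure
# signatures; the REFERENCE summary is on the Table-2 scale (USEPA16 ~1.9).
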