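"""Missense-variant triage with Grantham deviation, SIFT and PolyPhen.

Generates a 1,000-row missense table with a planted mix of damaging-vote
tiers (10% none / 20% one / 30% two / 40% three), assigns tiers with the
standard cutoffs (SIFT <= 0.05, PolyPhen >= 0.5, GD >= 65), and summarizes
variant classes and the regional density of missense variation on the
shipped TRPM8 domain map.
"""

import domevol as dv
from domevol.simulate import simulate_missense_table, simulate_variant_catalog

records, truth = simulate_missense_table(1000, tier_mix=(0.1, 0.2, 0.3, 0.4),
                                         seed=401)
dv.assign_tiers(records)
counts = dv.tier_counts(records)
print("damaging-vote tiers (green/blue/red triage):")
print(counts.to_string())
print("planted composition recovered exactly:",
      [r.vote_tier for r in records] == truth)

# GV/GD for one variant against an alignment column
gv, gd = dv.gvgd("RRRQ", "W")
print(f"\nGV/GD of X->W at a column observing R,R,R,Q: GV={gv:.1f}, GD={gd:.1f}")
print("-> GV is the physicochemical spread already tolerated at the column;")
print("   GD is how far the substitution falls outside it.")

catalog, _, _ = simulate_variant_catalog(2000, seed=402)
summary = dv.tally(catalog)
print("\nvariant classes (% of catalogue):")
print(summary.class_percent.round(1).to_string())

density = dv.positional_density(records, dv.trpm8_region_map())
density = density[density["region"].isin(["N-terminal", "TM and loop region",
                                          "C-terminal"])]
print("\nmissense density per residue by region:")
print(density.to_string(index=False))
print("-> the generator plants a 2:1 enrichment of the N-terminal domain.")
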