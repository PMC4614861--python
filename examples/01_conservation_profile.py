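"""Domain-resolved conservation profiling.

Simulates a 24-species protein family in which ten regions evolve at known
relative rates (0.2x to 2x), then scores each region by its mean pairwise
divergence and tests whether the regions really differ (Kruskal-Wallis).
Lower score = more conserved. On real data, swap in `read_alignment` and
`trpm8_region_map()` / `load_region_map()`.
"""

import numpy as np

import domevol as dv
from domevol.simulate import clock_tree, simulate_msa, uniform_region_map

mult_vals = np.linspace(0.2, 2.0, 10)
region_map = uniform_region_map(1104, 10, reference_id="t1")
multipliers = {f"R{i + 1:02d}": float(m) for i, m in enumerate(mult_vals)}

tree = clock_tree(24, depth=0.4, seed=101)
sim = simulate_msa(tree, 1104, rate=0.3, seed=102,
                   region_map=region_map, multipliers=multipliers)

scores = dv.score_regions(sim.alignment, region_map)
print(f"{'region':8} {'true rate':>9} {'mean div':>9} {'median':>8}")
for s in scores:  # ranked most conserved first
    print(f"{s.name:8} {multipliers[s.name]:9.2f} {s.mean:9.2f} {s.median:8.2f}")

hetero = dv.kruskal_wallis_regions(scores)
print(f"\nKruskal-Wallis H = {hetero.statistic:.1f}, p = {hetero.pvalue:.3g}")
print("-> region ranking tracks the planted rates; divergence (changes per")
print("   100 sites) differs significantly across regions.")
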