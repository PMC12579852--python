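"""Simulate daily field metabolic rate over the covariate grid.

Each Monte Carlo day fills a foraging budget with dive-recovery cycles and
a travel/search budget with breath-hold/inhalation cycles, converts the
summed daily inhalation time to tidal volume and FMR, and compares
covariate levels with Cohen's d across matched grid combinations.
"""

from whaleresp import FMRConfig, run_grid

config = FMRConfig(iterations=2000, seed=0)
result = run_grid(config)

cols = ["tl", "bai", "dive_duration", "tactic", "fmr_mean_mj", "prey_mean_t"]
print("extreme combinations:")
combos = result.combos.sort_values("fmr_mean_mj")
print(combos.head(1)[cols].round(3).to_string(index=False))
print(combos.tail(1)[cols].round(3).to_string(index=False))

print("\neffect sizes across matched pairs (Cohen's d, mean +/- sd):")
for _, row in result.comparisons.iterrows():
    print(f"  {row['family']:<28s} {row['d_mean']:5.2f} "
          f"+/- {row['d_sd']:.2f}  ({row['n_pairs']} pairs)")

# Body length dominates (d > 2): tidal volume scales with TL^2.  Tactic
# choice barely matters (d ~ 0.1).  d values are invariant to the heat
# coefficient H, which only scales absolute FMR.
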