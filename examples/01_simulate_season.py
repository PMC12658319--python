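"""Simulate one growing season for the default sorghum genotype.

Builds a synthetic Boone, IA season of hourly weather, runs the daily
physiological simulation from planting (May 27) to harvest (Oct 17) at the
trial-mean stand density, and prints biomass milestones.  Leaf and stem
weights are g dry matter per plant (main culm plus tillers); the final line
converts harvest-day shoot biomass to areal yield.
"""

import sorgsim as ss

weather = ss.generate_weather(2021, seed=1)
mgmt = ss.management_for_year(2021, stand_count=14.56)
genotype = ss.default_genotype()

trace = ss.simulate_season(genotype, weather, mgmt, is_ps=True)

print(f"{'day':>4} {'stage':<12} {'GDU':>7} {'leaf g':>7} {'stem g':>7} "
      f"{'height m':>8} {'tillers':>7}")
for day in (0, 22, 43, 64, 85, 110, 143):
    row = trace.data.iloc[day]
    print(f"{day:>4} {row['stage']:<12} {row['cumulative_gdu']:>7.0f} "
          f"{row['leaf_weight']:>7.1f} {row['stem_weight']:>7.1f} "
          f"{row['stem_height']:>8.2f} {row['tiller_count']:>7d}")

shoot = trace.final_shoot_biomass
print(f"\nharvest shoot biomass: {shoot:.1f} g/plant "
      f"= {shoot * mgmt.stand_count / 1000:.2f} kg/m2 at "
      f"{mgmt.stand_count} plants/m2")
print("note: the photoperiod-sensitive genotype stays vegetative all "
      "season, so all biomass is leaf + stem.")
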