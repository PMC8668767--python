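"""One miniature invasion scenario from start to finish.

Runs a 3x3 island for 100 burn-in years plus 200 invasion years under high
propagule pressure (10 individuals per year), then prints what the community
looks like: how many natives survived assembly, which introduced species
established, and which of those spread beyond the point of entry (making
them invasive by the landscape-spread definition).
"""

from invasim import ScenarioConfig, SpeciesCategory, run_scenario
from invasim.analysis import failed_introductions, run_categories

config = ScenarioConfig(
    side=3,
    burn_in=100,
    horizon=300,
    base_temperature=15.0,
    propagule_pressure=10,
    disturbance=0.01,
    rng_seed=1,
)
result = run_scenario(config)
world = result.world

print(f"final year {world.year}: {world.total_individuals()} plants on the island")
print(f"native species extant: {world.native_richness()}")
print(f"alien propagules introduced in total: {world.intro_tally.sum()} "
      f"({(world.intro_tally > 0).sum()} distinct species)")

cats = run_categories(result)
for cat in SpeciesCategory:
    members = sorted(s for s, c in cats.items() if c is cat)
    print(f"{cat.value:>8}: {len(members):2d} species {members}")
print(f"  failed: {len(failed_introductions(result)):2d} introduced species died out again")

invasives = [s for s, c in cats.items() if c is SpeciesCategory.INVASIVE]
final = result.final_census
for s in invasives:
    patches = final[final["species"] == s][["row", "col", "abundance"]]
    cells = ", ".join(f"({r.row},{r.col}) n={r.abundance}" for r in patches.itertuples())
    print(f"invasive {s} occupies: {cells}")
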