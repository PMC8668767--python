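# Methods

`invasim` is an individual-based, genetically explicit simulator of plant
community assembly and species invasion on a small gridded island, together
with a factorial in-silico experiment and a trait-analysis layer. This note
documents the model, its assumptions, the calibrated constants, and what the
synthetic setup does and does not capture.

## The island

A square grid (default 5x5) of one-hectare patches, each with a biomass
carrying capacity of 2 tonnes. Elevation rises in concentric rings
(Chebyshev-distance rings) toward the center cell; temperature drops 2 C per
elevation unit from the configurable lowland base temperature, giving a
radial temperature gradient. A second, abstract resource called
precipitation varies linearly across columns over a default range of 0–10
units. Continuous space exists only for seed dispersal: patch centers sit at
integer coordinates, cells are half-open unit squares, and any seed landing
outside the grid dies. One fixed mid-edge lowland cell on the dry side is
the point of entry for all introduced propagules.

Design choices here were genuinely open: the elevation profile is the
simplest ring geometry consistent with a radial gradient; the lowland base
temperature refers to the edge ring (not a sea-level datum); the entry cell
default is the mid-edge dry-side cell and is configurable.

## Plants, genomes, traits

Every plant carries a diploid genome: two haplotypes over a shared
gene-to-trait architecture. The default architecture has eight single-gene
chromosomes, one per trait, so traits recombine freely and are unlinked (a
deliberate choice mirroring the study's exclusion of mutation: genetic
confounds are kept out; the architecture is isolated behind a dataclass so a
pleiotropic or linked layout can be swapped in). A trait's phenotypic value
is the arithmetic mean of all alleles coding for it, clamped to the legal
domain. Mutation is off; phenotypes are immutable after creation.

The eight traits: temperature optimum and tolerance (C), precipitation
optimum and tolerance (abstract units), seed and adult mass (g; adult mass
is bounded to [150 g, 1.2 t], the grassland/shrubland range the model
represents), and the scale (grid units) and shape (dimensionless > 1) of the
log-logistic seed dispersal kernel.

Species are draws from a trait-generation process: niche optima uniform over
the island's realized environmental ranges widened by tolerance (a regional
pool broader than, but centered on, the island), tolerances and dispersal
parameters uniform, masses log-uniform (they span four orders of magnitude).
Default generation ranges:

| trait | range | draw |
|---|---|---|
| temperature optimum | realized island range ± 2 x tolerance cap | uniform |
| temperature tolerance | 0.5 – 4.5 C | uniform |
| precipitation optimum | precip range ± tolerance cap | uniform |
| precipitation tolerance | 0.5 – 4.5 | uniform |
| seed mass | 10 – 2000 g (capped at adult/2) | log-uniform |
| adult mass | 150 – 1.2e6 g | log-uniform |
| dispersal scale | 0.1 – 1.5 grid units | uniform |
| dispersal shape | 1.1 – 3.0 | uniform |

The seed-mass range was chosen so that the pool median (~140 g) sits near
the back-transformed pool medians implied by the published community tables
(~110 g); the same tables anchored the tolerance and dispersal medians.
Native and alien pools use the same generator — any trait difference between
categories at the end of a run is emergent, produced by centuries of
assembly and the invasion filter, not built in.

Individual variation: when a founder or introduced propagule is created,
one normal deviation per trait (SD = cv x |species mean|, default cv =
0.05) is written to both haplotypes. Founders are therefore homozygous and
their phenotypes are exactly Normal around the species means;
heterozygosity arises from crosses between founder lineages. Out-of-domain
draws are clamped rather than redrawn (bias is negligible at cv = 0.05).

Reproduction is sexual and local: each adult with at least one conspecific
adult in its patch acts once per year as mother with one partner drawn
uniformly from the others (no selfing; pollen does not cross patch borders —
gene flow between patches is carried by seeds only). Meiosis picks one
homolog per chromosome per gamete.

## Vital rates

Two Gaussian niche terms govern fitness: `G(b, c, x) = exp(-(x-b)^2/(2c^2))`
with optimum `b` and tolerance `c`, max-normalized so the peak value is 1
(the value is used as a survival/establishment weight in (0, 1], so a
probability-density normalization would be meaningless here). A plant's
combined adaptation is the product of its temperature and precipitation
terms against its own patch.

Metabolic (MTE) kernels set the pace of life:
`rate = coeff * M^b * exp(-E / (k T_kelvin))` with activation energy
E = 0.65 eV and Boltzmann's constant k = 8.617e-5 eV/K. Mortality scales as
M^(-1/4), production (growth and fecundity) as M^(3/4); every rate rises
with temperature. The three coefficients are calibrations — chosen once,
before any experiment, to produce plausible life histories, not literature
measurements:

* `m0 = 4.2e10`: a 1 kg plant with perfect temperature adaptation has ~5%
  baseline annual mortality at 20 C. Realized mortality divides the baseline
  by the plant's temperature adaptation (floored at 1e-6, capped at 1), so
  poorly adapted plants die faster — the division is the simplest coupling
  consistent with "mortality linked to temperature adaptation".
* `g0 = 2.8e11`: a 1 g seed reaches 1 kg adult mass in roughly 10 years at
  20 C. Growth stops at reproductive (adult) size.
* `f0 = 0.25`: an adult allocates a quarter of its annual MTE biomass
  production `g0 * M^(3/4) * exp(-E/kT)` to seeds; seed number is that
  allocation divided by the plant's seed mass, rounded. Plant reproductive
  effort in the field is typically some tens of percent of production, and
  with the seed-mass ranges above this value keeps median species viable
  (1–10 seeds per adult per year) without flooding patches with seedlings.

Competition for space: when a patch's summed biomass exceeds its capacity,
random pairs of plants compete and the one with the lower precipitation
adaptation is removed (ties broken by fair coin — no index-order bias) until
biomass fits or one plant remains.

Seed dispersal: distance from the mother is drawn from the log-logistic
kernel by inverse CDF, `d = a (u/(1-u))^(1/s)`; the scale `a` is the kernel
median (the "mean dispersal distance" trait is read as the scale parameter)
and the shape `s` controls the long-distance tail. Direction is uniform.
Seeds landing off the island die; seeds landing on a patch establish iff
their combined adaptation there reaches a hard threshold (default 0.05 —
"sufficiently adapted" read as a threshold). A Bernoulli mode, where a seed
establishes with probability equal to its adaptation, is available behind a
config flag.

Introduced propagules arrive at seed mass at the entry cell (arrival stage
is not otherwise specified; seeds are the conservative choice) and pass the
same establishment filter.

## The year loop and the experiment

Each simulated year applies, in fixed order: survival, growth, competition,
reproduction, disturbance, transport, dispersal. Disturbance (removal of a
fixed fraction of plants, species- and density-independent) and transport
(propagule-pressure many alien individuals, each of a species drawn
uniformly and independently from the 100-species alien pool) only begin
after the burn-in phase.

Initialization places, for every native pool species (default 50 attempted
founders) and every patch where its mean-trait adaptation clears the
establishment threshold, `floor(fill * capacity / adult_mass)` adults
(default fill 0.1), so small species start numerous and the realized
community is an emergent subset of the pool. Burn-in (default 500 years)
lets this community reach quasi-equilibrium; in default runs native richness
settles around six species, and richness at year 500 is almost always within
one species of its year-400 value.

The experiment harness crosses base temperature (15/35 C), propagule
pressure (1/10 per year) and disturbance (1%/10% per year) in a 2x2x2
factorial with any number of replicates. Per-run seeds are derived stably
from (base seed, replicate, scenario); species pools are derived from
(base seed, replicate) only, so scenarios differing in pressure or
disturbance share their pools within a replicate, enabling paired
comparisons (regenerating pools per run is available via
`--independent-pools`). All randomness flows through one generator per run:
a (config, seed) pair reproduces every output TSV byte for byte.

Census logs (every 50 years by default) record one row per population
(species x patch) with abundance, per-trait medians and variances
(population variance, ddof = 0), and the median individual adaptation.
Island maps are snapshotted at the end of burn-in and at the horizon.

## Analysis layer

At the final census each extant species is categorized: **native**
(original-community species still extant), **alien** (introduced, extant,
confined to the entry cell), **invasive** (introduced with at least one
population beyond the entry cell — the landscape-spread definition).
Introduced species that died out are tallied separately as "failed".
Categories are evaluated at the final census; a per-census time series is
available as an extra.

Invasion counts sum, per scenario, the number of invasive species over
replicates (one species invading in two runs counts twice). The exported
trait table holds one unweighted row per final population with
log(x+1)-transformed medians of dispersal scale, dispersal shape,
precipitation and temperature tolerance, adult and seed mass, and the
population adaptation (the Gaussian product evaluated at the population's
trait medians against its own patch). Temperature and precipitation optima
are excluded: they track geography and the temperature factor rather than
invasiveness. Downstream statistics (mixed models, simultaneous pairwise
tests, PCA ellipses) are deliberately out of scope: they are standard
routines over this table, and `examples/trait_summaries.py` sketches them.

## Problem sizes and numerical choices

The published headline experiment (5x5 island, 1500 years, 60 replicates x 8
scenarios) is a cluster-scale computation. This package's test suite and
acceptance script reproduce the qualitative results at a deliberately
miniature scale — 3x3 island, 100 burn-in + 200 invasion years, 20
replicates per scenario (160 runs) — chosen as the package's own reference
configuration for desk-scale verification. At that scale most directional
findings are stable: far more invasions under tenfold propagule pressure
(with near-perfect consistency across paired replicates), invasive
populations with higher adaptation than aliens, and invasives larger-bodied
and more precipitation-tolerant than natives.

One direction does **not** survive miniaturization: the pooled invasive
populations' median dispersal scale comes out at or below the natives'
rather than above it. The mechanism is geometric: on a 3x3 island the entry
cell sits on the edge, a large share of any high-dispersal plant's seeds
lands in the sea, and a single one-cell hop already counts as landscape
spread — so establishment selects against dispersal among invaders more
strongly than spread selects for it. On a larger island with a longer
invasion phase the spread advantage is expected to dominate, which is why
this particular contrast should be read only from full-scale runs.

Implementation notes that affect numerics:

* Population state is stored as float32 structure-of-arrays; genomes live in
  append-only allele pools referenced by index, so yearly compactions move
  4-byte references instead of genomes. Scientific quantities reported by
  tests (the adaptation oracle, kernel CDF checks) are computed in float64
  through the public scalar API.
* The competition loop, meiosis + phenotype expression, and the
  dispersal-fate evaluation are JIT-compiled (numba) with pure-numpy
  fallbacks that consume identical random streams.
* Ties in competition are broken by fair coin; equal-mass comparisons in
  growth use exact float equality (growth sets mass to exactly adult mass at
  the cap).
* Variances in the census use ddof = 0 so single-plant populations report 0
  rather than NaN.

## What the synthetic setup does not capture

No real-species parameters anywhere: species are abstract trait bundles.
No mutation or plasticity, no age structure, seed banks, herbivory or
facilitation; pollen does not cross patches; the landscape has no weather,
currents, or heterogeneous patch areas. Propagule arrivals are independent
uniform draws, so colonization pressure is an emergent byproduct rather than
a controlled factor. Passing tests therefore demonstrate internal
consistency of the model's mechanisms and the robustness of its qualitative
invasion results at miniature scale — not predictions for any real island,
and not the published experiment's exact numbers, which additionally depend
on appendix-level constants not restated in the main text.
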