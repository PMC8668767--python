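"""Species, diploid genomes, meiosis and phenotype expression.

Each plant carries a diploid genome: two haplotypes with an identical
gene-to-trait architecture. Genes hold real-valued alleles; a trait's
phenotypic value is the arithmetic mean of all alleles coding for it (both
haplotypes), clamped to the trait's legal domain. Mutation is off, so a
genome's phenotype never changes after creation; genetic variation enters
through founder trait noise and is reshuffled by meiosis.

The eight traits are: temperature optimum and tolerance, precipitation
optimum and tolerance (Gaussian niche parameters), seed and adult mass
(grams; the metabolic-rate and fecundity drivers), and the scale and shape of
the log-logistic seed dispersal kernel (grid units / dimensionless).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from functools import cached_property
from typing import Dict, Sequence, Tuple

import numpy as np

# trait indices, fixed order used by every array in the package
TOPT, TTOL, POPT, PTOL, SEED_MASS, ADULT_MASS, DSCALE, DSHAPE = range(8)

TRAIT_NAMES: Tuple[str, ...] = (
    "temp_optimum",
    "temp_tolerance",
    "precip_optimum",
    "precip_tolerance",
    "seed_mass",
    "adult_mass",
    "dispersal_scale",
    "dispersal_shape",
)

N_TRAITS = 8

# legal phenotype domain
ADULT_MASS_MIN_G = 150.0
ADULT_MASS_MAX_G = 1_200_000.0
TOL_MIN = 1e-2  # floor for niche tolerances, grams for seed mass, grid units
SHAPE_MIN = 1.0 + 1e-3  # dispersal shape must exceed 1 (finite kernel median)

MASS_TRAITS = frozenset({SEED_MASS, ADULT_MASS})  # drawn log-uniform


class ContractViolation(ValueError):
    """A caller broke one of the documented preconditions."""


class Origin(enum.Enum):
    NATIVE_POOL = "native"
    ALIEN_POOL = "alien"


def _clamp_inplace(out: np.ndarray) -> np.ndarray:
    np.maximum(out[..., TTOL], TOL_MIN, out=out[..., TTOL])
    np.maximum(out[..., PTOL], TOL_MIN, out=out[..., PTOL])
    np.clip(out[..., ADULT_MASS], ADULT_MASS_MIN_G, ADULT_MASS_MAX_G, out=out[..., ADULT_MASS])
    np.clip(out[..., SEED_MASS], TOL_MIN, out[..., ADULT_MASS] * (1.0 - 1e-9),
            out=out[..., SEED_MASS])
    np.maximum(out[..., DSCALE], TOL_MIN, out=out[..., DSCALE])
    np.maximum(out[..., DSHAPE], SHAPE_MIN, out=out[..., DSHAPE])
    return out


def clamp_trait_array(values: np.ndarray) -> np.ndarray:
    """Clamp an (..., 8) trait array into the legal phenotype domain.

    Tolerances and dispersal parameters are floored at small positive values,
    adult mass is clipped to [150 g, 1.2e6 g], and seed mass to
    (0, adult_mass) so every individual satisfies seed < adult.
    """
    return _clamp_inplace(np.array(values, dtype=float, copy=True))


@dataclass(frozen=True)
class TraitSet:
    """The eight phenotypic traits of one plant (or species means)."""

    temp_optimum: float
    temp_tolerance: float
    precip_optimum: float
    precip_tolerance: float
    seed_mass: float
    adult_mass: float
    dispersal_scale: float
    dispersal_shape: float

    def __post_init__(self):
        if not self.temp_tolerance > 0 or not self.precip_tolerance > 0:
            raise ContractViolation("niche tolerances must be strictly positive")
        if not ADULT_MASS_MIN_G <= self.adult_mass <= ADULT_MASS_MAX_G:
            raise ContractViolation(
                f"adult_mass {self.adult_mass} outside [{ADULT_MASS_MIN_G}, {ADULT_MASS_MAX_G}] g"
            )
        if not 0 < self.seed_mass < self.adult_mass:
            raise ContractViolation("seed_mass must lie in (0, adult_mass)")
        if not self.dispersal_scale > 0:
            raise ContractViolation("dispersal_scale must be strictly positive")
        if not self.dispersal_shape > 1:
            raise ContractViolation("dispersal_shape must exceed 1")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in TRAIT_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "TraitSet":
        return cls(**{n: float(v) for n, v in zip(TRAIT_NAMES, values)})


@dataclass(frozen=True)
class Architecture:
    """Gene-to-trait layout shared by both haplotypes of every species member.

    ``chromosomes`` groups gene indices into chromosomes (free recombination
    between chromosomes, none within); ``gene_traits`` maps each gene index to
    the trait it codes for. The default layout puts one single-gene chromosome
    per trait, so traits segregate independently.
    """

    chromosomes: Tuple[Tuple[int, ...], ...]
    gene_traits: Tuple[int, ...]

    def __post_init__(self):
        covered = {self.gene_traits[g] for chrom in self.chromosomes for g in chrom}
        if covered != set(range(N_TRAITS)):
            raise ContractViolation("every trait needs at least one coding gene")
        flat = sorted(g for chrom in self.chromosomes for g in chrom)
        if flat != list(range(len(self.gene_traits))):
            raise ContractViolation("chromosomes must partition the gene indices")

    @property
    def n_genes(self) -> int:
        return len(self.gene_traits)

    @cached_property
    def gene_chrom(self) -> np.ndarray:
        """Chromosome index of each gene, shape (n_genes,)."""
        out = np.empty(self.n_genes, dtype=np.int64)
        for ci, chrom in enumerate(self.chromosomes):
            for g in chrom:
                out[g] = ci
        return out

    @cached_property
    def trait_genes(self) -> Dict[int, np.ndarray]:
        """Trait index -> array of gene indices coding for it."""
        gt = np.asarray(self.gene_traits)
        return {t: np.flatnonzero(gt == t) for t in range(N_TRAITS)}

    @cached_property
    def is_trait_identity(self) -> bool:
        """True for the default layout: gene g codes trait g, 8 genes."""
        return self.gene_traits == tuple(range(N_TRAITS))


def default_architecture() -> Architecture:
    """One single-gene chromosome per trait (8 chromosomes)."""
    return Architecture(
        chromosomes=tuple((g,) for g in range(N_TRAITS)),
        gene_traits=tuple(range(N_TRAITS)),
    )


@dataclass(frozen=True)
class Genome:
    """Diploid genome: allele values with shape (2, n_genes)."""

    alleles: np.ndarray
    architecture: Architecture

    def __post_init__(self):
        a = np.asarray(self.alleles, dtype=float)
        if a.shape != (2, self.architecture.n_genes):
            raise ContractViolation(
                f"allele array must have shape (2, {self.architecture.n_genes}), got {a.shape}"
            )
        object.__setattr__(self, "alleles", a)


@dataclass(frozen=True)
class Species:
    species_id: str
    mean_traits: TraitSet
    origin: Origin
    architecture: Architecture = field(default_factory=default_architecture)


@dataclass
class Individual:
    """A plant: diploid genome, expressed phenotype, current mass, location."""

    id: int
    species_id: str
    genome: Genome
    phenotype: TraitSet
    mass: float
    location: Tuple[int, int]
    introduced: bool = False


# ---------------------------------------------------------------------------
# phenotype expression


def express_trait_matrix(alleles: np.ndarray, architecture: Architecture) -> np.ndarray:
    """Vectorized expression: (N, 2, n_genes) alleles -> clamped (N, 8) traits."""
    if architecture.is_trait_identity:
        return _clamp_inplace(alleles.mean(axis=1))
    n = alleles.shape[0]
    phen = np.empty((n, N_TRAITS), dtype=float)
    for t, genes in architecture.trait_genes.items():
        phen[:, t] = alleles[:, :, genes].mean(axis=(1, 2))
    return _clamp_inplace(phen)


def express_phenotype(genome: Genome) -> TraitSet:
    """Mean of all alleles coding for each trait, clamped to the legal domain."""
    phen = express_trait_matrix(genome.alleles[None, :, :], genome.architecture)[0]
    return TraitSet.from_array(phen)


# ---------------------------------------------------------------------------
# species generation


@dataclass(frozen=True)
class TraitRanges:
    """Per-trait (lo, hi) generation ranges for random species pools.

    Mass traits are drawn log-uniform (they span several orders of magnitude);
    every other trait is drawn uniform. Seed mass is additionally capped at
    half the drawn adult mass so seeds are always much lighter than adults.
    """

    temp_optimum: Tuple[float, float] = (3.0, 24.0)
    temp_tolerance: Tuple[float, float] = (0.5, 4.5)
    precip_optimum: Tuple[float, float] = (-4.5, 14.5)
    precip_tolerance: Tuple[float, float] = (0.5, 4.5)
    seed_mass: Tuple[float, float] = (10.0, 2000.0)
    adult_mass: Tuple[float, float] = (ADULT_MASS_MIN_G, ADULT_MASS_MAX_G)
    dispersal_scale: Tuple[float, float] = (0.1, 1.5)
    dispersal_shape: Tuple[float, float] = (1.1, 3.0)

    def __post_init__(self):
        for name in TRAIT_NAMES:
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ContractViolation(f"inverted range for {name}: ({lo}, {hi})")
            if name in ("seed_mass", "adult_mass") and lo <= 0:
                raise ContractViolation(f"{name} range must be positive")

    @classmethod
    def for_island(
        cls,
        realized_temperature_range: Tuple[float, float],
        precip_range: Tuple[float, float],
        temp_tolerance: Tuple[float, float] = (0.5, 4.5),
        precip_tolerance: Tuple[float, float] = (0.5, 4.5),
        **overrides,
    ) -> "TraitRanges":
        """Niche-optimum ranges anchored to the island's realized environment.

        Temperature optima span the realized temperature range widened by
        twice the upper tolerance; precipitation optima span the precipitation
        gradient widened by one upper tolerance. Species are therefore drawn
        from a regional pool that is broader than, but centered on, the island.
        """
        t_lo, t_hi = realized_temperature_range
        p_lo, p_hi = precip_range
        return cls(
            temp_optimum=(t_lo - 2 * temp_tolerance[1], t_hi + 2 * temp_tolerance[1]),
            temp_tolerance=temp_tolerance,
            precip_optimum=(p_lo - precip_tolerance[1], p_hi + precip_tolerance[1]),
            precip_tolerance=precip_tolerance,
            **overrides,
        )


def _draw(rng: np.random.Generator, lo: float, hi: float, log: bool) -> float:
    if lo == hi:
        return float(lo)
    if log:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return float(rng.uniform(lo, hi))


def random_species(
    rng: np.random.Generator,
    trait_ranges: TraitRanges,
    origin: Origin,
    species_id: str,
    architecture: Architecture | None = None,
) -> Species:
    """Draw one species' mean traits from the generation ranges.

    Draw order is fixed (niche traits, adult mass, seed mass, dispersal), so
    a given generator state always yields the same species. Adult mass is
    drawn before seed mass because the seed range is truncated at adult/2.
    """
    arch = architecture or default_architecture()
    vals = np.empty(N_TRAITS)
    vals[TOPT] = _draw(rng, *trait_ranges.temp_optimum, log=False)
    vals[TTOL] = _draw(rng, *trait_ranges.temp_tolerance, log=False)
    vals[POPT] = _draw(rng, *trait_ranges.precip_optimum, log=False)
    vals[PTOL] = _draw(rng, *trait_ranges.precip_tolerance, log=False)
    vals[ADULT_MASS] = _draw(rng, *trait_ranges.adult_mass, log=True)
    s_lo, s_hi = trait_ranges.seed_mass
    s_hi = min(s_hi, vals[ADULT_MASS] / 2.0)
    s_lo = min(s_lo, s_hi)
    vals[SEED_MASS] = _draw(rng, s_lo, s_hi, log=True)
    vals[DSCALE] = _draw(rng, *trait_ranges.dispersal_scale, log=False)
    vals[DSHAPE] = _draw(rng, *trait_ranges.dispersal_shape, log=False)
    return Species(
        species_id=species_id,
        mean_traits=TraitSet.from_array(clamp_trait_array(vals)),
        origin=origin,
        architecture=arch,
    )


# ---------------------------------------------------------------------------
# individual creation and meiosis


def founder_alleles(
    species_means: np.ndarray,
    rng: np.random.Generator,
    cv: float,
    architecture: Architecture,
) -> np.ndarray:
    """Allele arrays for newly created (founder or introduced) individuals.

    ``species_means`` has shape (N, 8). One normal deviation per trait per
    individual, SD = cv * |mean|, written to every gene coding for the trait
    on both haplotypes: founders are homozygous, so an individual's phenotype
    is Normal(species mean, cv * |mean|) before clamping, and heterozygosity
    arises only from later crosses between founder lineages.
    """
    n = species_means.shape[0]
    if cv < 0:
        raise ContractViolation("cv must be non-negative")
    devs = species_means + cv * np.abs(species_means) * rng.standard_normal((n, N_TRAITS))
    devs = clamp_trait_array(devs)
    alleles = np.empty((n, 2, architecture.n_genes))
    for t, genes in architecture.trait_genes.items():
        alleles[:, :, genes] = devs[:, t][:, None, None]
    return alleles


def spawn_individual(
    species: Species,
    rng: np.random.Generator,
    cv: float = 0.05,
    stage: str = "seed",
    location: Tuple[int, int] = (0, 0),
    individual_id: int = 0,
    introduced: bool = False,
) -> Individual:
    """Create one individual of a species with founder trait noise.

    ``stage`` selects the starting mass: ``"seed"`` (seed mass, for dispersing
    or introduced propagules) or ``"adult"`` (adult mass, for initialization
    founders).
    """
    alleles = founder_alleles(species.mean_traits.as_array()[None, :], rng, cv, species.architecture)[0]
    genome = Genome(alleles=alleles, architecture=species.architecture)
    phen = express_phenotype(genome)
    if stage == "seed":
        mass = phen.seed_mass
    elif stage == "adult":
        mass = phen.adult_mass
    else:
        raise ContractViolation(f"unknown stage {stage!r}")
    return Individual(
        id=individual_id,
        species_id=species.species_id,
        genome=genome,
        phenotype=phen,
        mass=mass,
        location=location,
        introduced=introduced,
    )


def meiosis_batch(
    mother_alleles: np.ndarray,
    father_alleles: np.ndarray,
    architecture: Architecture,
    rng: np.random.Generator,
) -> np.ndarray:
    """Offspring allele arrays from paired parents, shape (N, 2, n_genes).

    For each offspring, each gamete independently picks one homolog per
    chromosome (uniformly) from its parent: free recombination between
    chromosomes, none within. Haplotype 0 is the maternal gamete, 1 paternal.
    """
    n = mother_alleles.shape[0]
    rows = np.arange(n)
    out = np.empty_like(mother_alleles)
    out[:, 0, :] = gather_gametes(mother_alleles, rows, architecture, rng)
    out[:, 1, :] = gather_gametes(father_alleles, rows, architecture, rng)
    return out


def gather_gametes(
    alleles: np.ndarray,
    parent_rows: np.ndarray,
    architecture: Architecture,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per entry of ``parent_rows``, drawn from ``alleles``.

    ``alleles`` is any (N, 2, n_genes) array; ``parent_rows`` indexes into it
    (repeats allowed). Each gamete picks one homolog per chromosome. Gathering
    through flat indices avoids materializing per-offspring parent copies.
    """
    n = parent_rows.shape[0]
    g = architecture.n_genes
    n_chrom = len(architecture.chromosomes)
    pick = rng.integers(0, 2, size=(n, n_chrom), dtype=np.int8)[:, architecture.gene_chrom]
    flat = (parent_rows[:, None] * 2 + pick) * g + np.arange(g)[None, :]
    return np.take(alleles.reshape(-1), flat)


def mate(mother: Individual, father: Individual, rng: np.random.Generator) -> Genome:
    """One offspring genome from two conspecific, distinct, co-located parents.

    Self-pollination is not permitted, pollen does not travel between patches,
    and parents must belong to the same species.
    """
    if mother.id == father.id:
        raise ContractViolation("self-pollination is not permitted")
    if mother.species_id != father.species_id:
        raise ContractViolation("parents must be conspecific")
    if mother.location != father.location:
        raise ContractViolation("pollen dispersal is restricted to the local grid cell")
    arch = mother.genome.architecture
    child = meiosis_batch(
        mother.genome.alleles[None, :, :], father.genome.alleles[None, :, :], arch, rng
    )[0]
    return Genome(alleles=child, architecture=arch)
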