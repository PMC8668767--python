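"""Yearly demographic processes and their shared kernels.

Three kernels drive all vital rates:

* **Gaussian niche adaptation** — a plant's adaptation to its patch is
  ``A = G(Topt, Ttol, Tenv) * G(Popt, Ptol, Penv)`` where
  ``G(b, c, x) = exp(-(x - b)^2 / (2 c^2))`` is the max-normalized Gaussian
  (peak value 1 at the optimum). The temperature component scales mortality;
  the precipitation component decides pairwise competition; the product
  gates seed establishment.

* **Metabolic Theory of Ecology (MTE) rates** — mass- and temperature-
  dependent rates of the form ``coeff * M^b * exp(-E / (k T))`` with
  allometric exponent b = 3/4 for production (growth, fecundity) and -1/4
  for mortality, activation energy E in eV and Boltzmann's constant k in
  eV/K. Larger plants therefore live longer and make more seeds; warmer
  patches speed up every rate.

* **Log-logistic dispersal kernel** — seed displacement distance is sampled
  by inverse CDF, ``d = a * (u / (1 - u))^(1/s)``; the scale ``a`` is the
  kernel median (grid units) and smaller shapes ``s`` give heavier tails
  (more long-distance dispersal).

The seven yearly processes operate on patches in this fixed order:
survival, growth, competition, reproduction, disturbance, transport
(introduction of aliens at the point of entry), and seed dispersal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from ._kernels import compete_loop, dispersal_fate_loop, max_removals, meiosis_express_loop
from .genetics import (
    ADULT_MASS,
    ADULT_MASS_MAX_G,
    ADULT_MASS_MIN_G,
    POPT,
    PTOL,
    SEED_MASS,
    SHAPE_MIN,
    TOL_MIN,
    TOPT,
    TTOL,
    Architecture,
    ContractViolation,
    TraitSet,
    express_trait_matrix,
    founder_alleles,
    gather_gametes,
)
from .landscape import Island, Patch
from .population import Population

BOLTZMANN_EV_K = 8.617e-5

#: floor applied to the temperature-adaptation divisor in the mortality rate
ADAPTATION_FLOOR = 1e-6


@dataclass(frozen=True)
class MTEConstants:
    """Constants of the metabolic vital-rate kernels.

    Defaults are calibrated (not literature measurements) so that at 20 C a
    1 kg plant with perfect temperature adaptation has ~5% baseline annual
    mortality, a 1 g seed grows to 1 kg adult mass in ~10 years, and an adult
    allocates a quarter of its annual biomass production to seeds. These anchors give
    multi-decade life cycles and a community that equilibrates within a few
    hundred simulated years.
    """

    activation_energy: float = 0.65  # eV
    boltzmann: float = BOLTZMANN_EV_K  # eV/K
    mort_coeff: float = 4.2e10  # g^(1/4) yr^-1 scale
    growth_coeff: float = 2.8e11  # g^(1/4) yr^-1 scale
    fecund_fraction: float = 0.25  # fraction of production allocated to seeds

    def __post_init__(self):
        for name in ("activation_energy", "boltzmann", "mort_coeff", "growth_coeff", "fecund_fraction"):
            if getattr(self, name) < 0:
                raise ContractViolation(f"{name} must be non-negative")


@dataclass(frozen=True)
class AdaptationValue:
    """Temperature, precipitation and combined adaptation, each in (0, 1]."""

    temp_component: float
    precip_component: float

    @property
    def combined(self) -> float:
        return self.temp_component * self.precip_component


def gauss(b, c, x):
    """Max-normalized Gauss function ``exp(-(x-b)^2 / (2 c^2))``.

    ``b`` is the optimum, ``c`` the tolerance (standard deviation, > 0) and
    ``x`` the environmental value. Accepts scalars or arrays.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ContractViolation("tolerance c must be strictly positive")
    b = np.asarray(b, dtype=float)
    x = np.asarray(x, dtype=float)
    out = np.exp(-((x - b) ** 2) / (2.0 * c**2))
    return float(out) if out.ndim == 0 else out


def adaptation(traits: TraitSet, patch: Patch) -> AdaptationValue:
    """Adaptation of a phenotype to a patch: product of the two niche terms."""
    return AdaptationValue(
        temp_component=gauss(traits.temp_optimum, traits.temp_tolerance, patch.temperature),
        precip_component=gauss(traits.precip_optimum, traits.precip_tolerance, patch.precipitation),
    )


def adaptation_components(phen: np.ndarray, temperature: float, precipitation: float):
    """Vectorized (A_T, A_P) for an (N, 8) phenotype matrix."""
    a_t = gauss(phen[:, TOPT], phen[:, TTOL], temperature)
    a_p = gauss(phen[:, POPT], phen[:, PTOL], precipitation)
    return a_t, a_p


def arrhenius(temperature_c, constants: MTEConstants):
    """Boltzmann-Arrhenius temperature factor ``exp(-E / (k (T + 273.15)))``."""
    t_k = np.asarray(temperature_c, dtype=float) + 273.15
    out = np.exp(-constants.activation_energy / (constants.boltzmann * t_k))
    return float(out) if out.ndim == 0 else out


def mte_rate(mass, temperature_c, exponent: float, coeff: float, constants: MTEConstants):
    """MTE rate ``coeff * M^exponent * exp(-E / (k T))`` per year."""
    m = np.asarray(mass, dtype=float)
    if np.any(m <= 0):
        raise ContractViolation("mass must be strictly positive")
    out = coeff * m**exponent * arrhenius(temperature_c, constants)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# yearly processes (each operates on one patch and returns removed/new plants)


def survival_step(
    patch: Patch,
    constants: MTEConstants,
    rng: np.random.Generator,
    collect_removed: bool = True,
) -> Population:
    """Density-independent mortality, worse for poorly temperature-adapted plants.

    Each plant dies independently with probability
    ``min(1, m0 * M^(-1/4) * exp(-E/kT) / max(A_T, eps))``.
    Returns the removed individuals (an empty population when
    ``collect_removed`` is off, which the year loop uses to skip the copy).
    """
    pop: Population = patch.individuals
    if len(pop) == 0:
        return Population.empty(pop.architecture)
    a_t, _ = pop.ensure_adaptation(patch.temperature, patch.precipitation)
    # m0 * M^(-1/4) * arr, with M^(1/4) as two square roots (cheaper than pow)
    scale = constants.mort_coeff * arrhenius(patch.temperature, constants)
    base = scale / np.sqrt(np.sqrt(pop.mass))
    p = np.minimum(1.0, base / np.maximum(a_t, ADAPTATION_FLOOR))
    dead = rng.random(len(pop)) < p
    patch.individuals = pop.subset(~dead)
    return pop.subset(dead) if collect_removed else Population.empty(pop.architecture)


def growth_step(patch: Patch, constants: MTEConstants) -> None:
    """Plants below their reproductive size grow by the MTE production rate."""
    pop: Population = patch.individuals
    if len(pop) == 0:
        return
    adult = pop.phen[:, ADULT_MASS]
    juvenile = pop.mass < adult
    if not juvenile.any():
        return
    mj = pop.mass[juvenile]
    # g0 * M^(3/4) * arr, with M^(3/4) = M / M^(1/4)
    inc = (constants.growth_coeff * arrhenius(patch.temperature, constants)) * (
        mj / np.sqrt(np.sqrt(mj))
    )
    pop.mass[juvenile] = np.minimum(adult[juvenile], mj + inc)


def competition_step(
    patch: Patch, rng: np.random.Generator, collect_removed: bool = True
) -> Population:
    """Density-dependent mortality once patch biomass exceeds its capacity.

    Random pairs of plants compete; the one with the lower precipitation
    adaptation is removed (ties by fair coin) until total biomass fits the
    carrying capacity or a single plant remains. Returns the removed plants.
    """
    pop: Population = patch.individuals
    if len(pop) < 2 or pop.biomass <= patch.capacity:
        return Population.empty(pop.architecture)
    _, a_p = pop.ensure_adaptation(patch.temperature, patch.precipitation)
    k = max_removals(pop.mass, patch.capacity)
    rand = rng.random(3 * k + 3)
    alive = compete_loop(pop.mass.astype(np.float64), a_p.astype(np.float64), patch.capacity, rand)
    patch.individuals = pop.subset(alive)
    return pop.subset(~alive) if collect_removed else Population.empty(pop.architecture)


def reproduction_step(
    patch: Patch,
    constants: MTEConstants,
    rng: np.random.Generator,
    ids,
) -> Population:
    """Sexual reproduction of co-located conspecific adults; returns the seeds.

    Every adult (mass at reproductive size) with at least one conspecific
    adult partner in the patch acts once as mother; its partner is drawn
    uniformly from the other conspecific adults (no selfing, no cross-patch
    pollen). Seed number is the seed-mass quotient of the mother's allocated
    production, ``round(f0 * g0 * M^(3/4) * exp(-E/kT) / seed_mass)``;
    each seed's genome comes from meiosis of both parents. Seeds carry the
    mother's patch as their dispersal origin and are not yet residents.
    """
    pop: Population = patch.individuals
    empty = Population.empty(pop.architecture)
    if len(pop) < 2:
        return empty
    adult_mask = pop.mass >= pop.phen[:, ADULT_MASS]
    if int(adult_mask.sum()) < 2:
        return empty
    arr = arrhenius(patch.temperature, constants)
    adult_idx = np.flatnonzero(adult_mask)
    sp = pop.species[adult_idx]
    order = np.argsort(sp, kind="stable")
    adult_idx = adult_idx[order]
    sp_sorted = sp[order]
    _, counts = np.unique(sp_sorted, return_counts=True)
    k_per_adult = np.repeat(counts, counts)
    # only adults with at least one conspecific adult partner reproduce
    paired = k_per_adult >= 2
    if not paired.any():
        return empty
    adult_idx = adult_idx[paired]
    sp_sorted = sp_sorted[paired]
    k_per_adult = k_per_adult[paired]
    counts = counts[counts >= 2]
    group_start = np.repeat(np.cumsum(counts) - counts, counts)
    local = np.arange(len(adult_idx)) - group_start
    # one partner per mother, drawn among the other k-1 conspecific adults
    draws = rng.integers(0, k_per_adult - 1)
    partner_local = draws + (draws >= local)
    father_of_mother = adult_idx[group_start + partner_local]
    mass = pop.mass[adult_idx]
    seed_mass = pop.phen[adult_idx, SEED_MASS]
    production = (constants.fecund_fraction * constants.growth_coeff * arr) * (
        mass.astype(np.float64) / np.sqrt(np.sqrt(mass, dtype=np.float64))
    )
    n_seeds = np.maximum(np.rint(production / seed_mass).astype(np.int64), 0)
    total = int(n_seeds.sum())
    if total == 0:
        return empty
    mothers = np.repeat(adult_idx, n_seeds)
    fathers = np.repeat(father_of_mother, n_seeds)
    seed_species = np.repeat(sp_sorted, n_seeds)
    arch = pop.architecture
    refs_m = np.take(pop.refs, mothers).astype(np.int64)
    refs_f = np.take(pop.refs, fathers).astype(np.int64)
    child = np.empty((total, 2, arch.n_genes), dtype=pop.pool.data.dtype)
    if arch.is_trait_identity:
        # fused meiosis + expression kernel (one pass over the seed rain)
        n_chrom = len(arch.chromosomes)
        picks_m = rng.integers(0, 2, size=(total, n_chrom), dtype=np.int8)
        picks_f = rng.integers(0, 2, size=(total, n_chrom), dtype=np.int8)
        phen = np.empty((total, 8), dtype=pop.pool.data.dtype)
        meiosis_express_loop(
            pop.pool.data, refs_m, refs_f, picks_m, picks_f, child, phen,
            TOL_MIN, SHAPE_MIN, ADULT_MASS_MIN_G, ADULT_MASS_MAX_G,
        )
    else:
        child[:, 0, :] = gather_gametes(pop.pool.data, refs_m, arch, rng)
        child[:, 1, :] = gather_gametes(pop.pool.data, refs_f, arch, rng)
        phen = express_trait_matrix(child, arch)
    return Population(
        ids=ids.take(total),
        species=seed_species,
        alleles=child,
        phen=phen,
        mass=phen[:, SEED_MASS].copy(),
        introduced=np.zeros(total, dtype=bool),
        architecture=pop.architecture,
    )


def disturbance_step(
    patch: Patch, d: float, rng: np.random.Generator, collect_removed: bool = True
) -> Population:
    """Species- and density-independent removal of a fraction d of plants."""
    if not 0.0 <= d <= 1.0:
        raise ContractViolation(f"disturbance fraction must be in [0, 1], got {d}")
    pop: Population = patch.individuals
    if len(pop) == 0 or d == 0.0:
        return Population.empty(pop.architecture)
    dead = rng.random(len(pop)) < d
    patch.individuals = pop.subset(~dead)
    return pop.subset(dead) if collect_removed else Population.empty(pop.architecture)


def transport_step(
    island: Island,
    alien_means: np.ndarray,
    alien_species_indices: np.ndarray,
    pressure: int,
    rng: np.random.Generator,
    *,
    year: int,
    burn_in: int,
    cv: float,
    threshold: float,
    architecture: Architecture,
    ids,
    bernoulli: bool = False,
) -> Tuple[Population, np.ndarray]:
    """Introduce ``pressure`` alien propagules at the point of entry.

    Each propagule's species is drawn independently and uniformly from the
    alien pool, so a year's arrivals can contain several plants of one
    species. Arrivals enter at seed mass and pass the same establishment
    filter as dispersing seeds (combined adaptation against the entry
    patch's environment). Returns (established arrivals, drawn pool rows);
    established arrivals are appended to the entry patch.
    """
    if year <= burn_in:
        raise ContractViolation("transport must not run during the burn-in period")
    if pressure < 0:
        raise ContractViolation("propagule pressure must be non-negative")
    n_pool = alien_means.shape[0]
    if n_pool == 0:
        raise ContractViolation("alien pool is empty")
    entry = island.entry_patch
    if pressure == 0:
        return Population.empty(architecture), np.empty(0, dtype=np.int64)
    drawn = rng.integers(0, n_pool, size=pressure)
    alleles = founder_alleles(alien_means[drawn], rng, cv, architecture)
    phen = express_trait_matrix(alleles, architecture)
    a_t, a_p = adaptation_components(phen, entry.temperature, entry.precipitation)
    aind = a_t * a_p
    if bernoulli:
        ok = rng.random(pressure) < aind
    else:
        ok = aind >= threshold
    arrivals = Population(
        ids=ids.take(pressure),
        species=np.asarray(alien_species_indices)[drawn].astype(np.int32),
        alleles=alleles,
        phen=phen,
        mass=phen[:, SEED_MASS].copy(),
        introduced=np.ones(pressure, dtype=bool),
        architecture=architecture,
        a_t=a_t,
        a_p=a_p,
        adapt_env=(float(entry.temperature), float(entry.precipitation)),
    )
    established = arrivals.subset(ok)
    entry.individuals = entry.individuals.extend(established)
    return established, drawn


def sample_dispersal_distance(a, s, rng: np.random.Generator, size=None):
    """Sample displacement distances from the log-logistic dispersal kernel.

    Inverse-CDF sampling: ``d = a * (u / (1 - u))^(1/s)`` with u ~ U(0, 1).
    The scale ``a`` (> 0) is the distribution median; the shape ``s`` (> 1)
    controls tail heaviness (smaller s, heavier tail). ``a`` and ``s`` may be
    arrays broadcast against ``size``.
    """
    a = np.asarray(a, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(a <= 0):
        raise ContractViolation("dispersal scale must be strictly positive")
    if np.any(s <= 1):
        raise ContractViolation("dispersal shape must exceed 1")
    u = rng.random(size if size is not None else np.broadcast(a, s).shape or None)
    out = a * (u / (1.0 - u)) ** (1.0 / s)
    return float(out) if np.ndim(out) == 0 else out


def dispersal_step(
    island: Island,
    seed_batches: Sequence[Tuple[int, int, Population]],
    rng: np.random.Generator,
    threshold: float,
    bernoulli: bool = False,
) -> Tuple[Population, dict]:
    """Disperse this year's seeds and establish the survivors.

    Each seed moves from its natal patch center by a kernel-sampled distance
    in a uniform random direction. Seeds landing beyond the island borders
    die; seeds landing on a patch establish iff their combined adaptation to
    that patch reaches the establishment threshold (or, in Bernoulli mode,
    with probability equal to their adaptation). Established seeds join the
    landing patch. Returns (established seeds, bookkeeping counts).
    """
    arch = seed_batches[0][2].architecture if seed_batches else None
    pools = [b for _, _, b in seed_batches if len(b) > 0]
    stats = {"produced": 0, "off_island": 0, "unsuitable": 0, "established": 0}
    if not pools:
        return Population.empty(arch), stats
    seeds = Population(
        np.concatenate([b.ids for b in pools]),
        np.concatenate([b.species for b in pools]),
        alleles=np.concatenate([b.pool.data[: b.pool.n] for b in pools]),
        phen=np.concatenate([b.phen for b in pools]),
        mass=np.concatenate([b.mass for b in pools]),
        introduced=np.concatenate([b.introduced for b in pools]),
        architecture=pools[0].architecture,
    )
    src_row = np.concatenate(
        [np.full(len(b), r, dtype=float) for r, _, b in seed_batches if len(b) > 0]
    )
    src_col = np.concatenate(
        [np.full(len(b), c, dtype=float) for _, c, b in seed_batches if len(b) > 0]
    )
    n = len(seeds)
    stats["produced"] = n
    u_dist = rng.random(n)
    u_ang = rng.random(n)
    temps = island.temperatures
    precs = np.array([[p.precipitation for p in r] for r in island.patches])
    row = np.zeros(n, dtype=np.int64)
    col = np.zeros(n, dtype=np.int64)
    a_t_all = np.zeros(n)
    a_p_all = np.zeros(n)
    on = np.zeros(n, dtype=bool)
    # fused pass: kernel displacement sample, landing cell, niche terms
    dispersal_fate_loop(
        seeds.phen, src_row, src_col, u_dist, u_ang, temps, precs, island.side,
        row, col, a_t_all, a_p_all, on,
    )
    stats["off_island"] = int(n - on.sum())
    aind = a_t_all * a_p_all
    if bernoulli:
        ok = on & (rng.random(n) < aind)
    else:
        ok = on & (aind >= threshold)
    stats["unsuitable"] = int(on.sum() - ok[on].sum())
    stats["established"] = int(ok.sum())
    established = seeds.subset(ok)
    if len(established):
        cell = row[ok] * island.side + col[ok]
        order = np.argsort(cell, kind="stable")
        cell_sorted = cell[order]
        uniq, starts = np.unique(cell_sorted, return_index=True)
        bounds = np.append(starts, len(cell_sorted))
        est_rows = np.flatnonzero(ok)
        for u, s0, e0 in zip(uniq, bounds[:-1], bounds[1:]):
            patch = island.patch(int(u) // island.side, int(u) % island.side)
            pick = order[s0:e0]
            arrivals = established.subset(pick)
            arrivals.a_t = a_t_all[est_rows[pick]].astype(Population.DTYPE)
            arrivals.a_p = a_p_all[est_rows[pick]].astype(Population.DTYPE)
            arrivals.adapt_env = (float(patch.temperature), float(patch.precipitation))
            patch.individuals = patch.individuals.extend(arrivals)
    return established, stats
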