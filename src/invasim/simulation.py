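"""Scenario configuration, world initialization, the year loop, and the
full-factorial experiment harness.

A run starts from a randomly generated native species pool whose founders are
placed as adults in every patch they are sufficiently adapted to, with
founder numbers inversely proportional to adult mass (small species start
numerous). The community then runs through a burn-in phase (default 500
years) to reach quasi-equilibrium. After burn-in, two pressures begin: a
yearly disturbance removing a fixed fraction of plants, and yearly transport
of alien propagules (drawn from a separate 100-species global pool) to the
fixed point of entry. The run ends at the horizon (default 1500 years).

Every 50 years a census records, per population (species x patch), the
abundance, the median and variance of each trait, and the median individual
adaptation. Island maps (species x patch x abundance) are snapshotted at the
end of burn-in and at the horizon. All randomness flows through a single
seeded generator per run, so (config, seed) determines every output byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import demography as dem
from .demography import MTEConstants
from .genetics import (
    ADULT_MASS,
    TRAIT_NAMES,
    Origin,
    Species,
    TraitRanges,
    default_architecture,
    express_trait_matrix,
    founder_alleles,
    random_species,
)
from .landscape import ConfigurationError, Island, build_island
from .population import IdCounter, Population

CENSUS_FLOAT_FORMAT = "%.10g"


@dataclass
class ScenarioConfig:
    """One cell of the factorial design plus run control.

    The three experimental factors are ``base_temperature`` (productivity
    proxy; printed levels 15 / 35 C), ``propagule_pressure`` (1 / 10
    individuals per year) and ``disturbance`` (0.01 / 0.10 fraction per
    year). The printed levels are defaults, not constraints.
    """

    base_temperature: float = 15.0
    propagule_pressure: int = 1
    disturbance: float = 0.01
    burn_in: int = 500
    horizon: int = 1500
    n_native_pool: int = 50
    n_alien_pool: int = 100
    replicate_id: int = 0
    rng_seed: int = 0
    pool_seed: Optional[int] = None  # defaults to rng_seed; set by the harness
    side: int = 5
    precip_range: Tuple[float, float] = (0.0, 10.0)
    entry_cell: Optional[Tuple[int, int]] = None
    census_interval: int = 50
    establishment_threshold: float = 0.05
    bernoulli_establishment: bool = False
    founder_fill: float = 0.1
    trait_cv: float = 0.05
    mte: MTEConstants = field(default_factory=MTEConstants)
    trait_ranges: Optional[TraitRanges] = None  # None: derived from the island

    def __post_init__(self):
        if self.burn_in > self.horizon:
            raise ConfigurationError("burn_in must not exceed horizon")
        if self.census_interval < 1:
            raise ConfigurationError("census_interval must be >= 1")
        if not 0.0 <= self.disturbance <= 1.0:
            raise ConfigurationError("disturbance must be a fraction in [0, 1]")
        if self.propagule_pressure < 0:
            raise ConfigurationError("propagule_pressure must be non-negative")
        if self.n_alien_pool < 1:
            raise ConfigurationError("alien pool must contain at least one species")

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        data = dict(data)
        if "mte" in data and isinstance(data["mte"], dict):
            data["mte"] = MTEConstants(**data["mte"])
        if "trait_ranges" in data and isinstance(data["trait_ranges"], dict):
            data["trait_ranges"] = TraitRanges(
                **{k: tuple(v) for k, v in data["trait_ranges"].items()}
            )
        for key in ("precip_range", "entry_cell"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config file must hold a mapping of keys")
        return cls.from_dict(data)

    def resolved_constants_header(self) -> List[str]:
        """TSV comment lines echoing every resolved kernel constant."""
        m = self.mte
        return [
            f"# propagule_pressure={self.propagule_pressure}",
            f"# disturbance={self.disturbance}",
            f"# burn_in={self.burn_in} horizon={self.horizon}",
            f"# rng_seed={self.rng_seed} pool_seed={self.pool_seed if self.pool_seed is not None else self.rng_seed}",
            f"# mte E={m.activation_energy} k={m.boltzmann} m0={m.mort_coeff} g0={m.growth_coeff} f0={m.fecund_fraction}",
            f"# establishment_threshold={self.establishment_threshold} bernoulli={self.bernoulli_establishment}",
            f"# founder_fill={self.founder_fill} trait_cv={self.trait_cv}",
            f"# n_native_pool={self.n_native_pool} n_alien_pool={self.n_alien_pool}",
        ]


class WorldState:
    """Full mutable state of one simulation run."""

    def __init__(self, config: ScenarioConfig, island: Island, registry: List[Species],
                 means: np.ndarray, n_native: int, rng: np.random.Generator):
        self.config = config
        self.island = island
        self.registry = registry
        self.means = means
        self.n_native = n_native
        self.rng = rng
        self.year = 0
        self.ids = IdCounter()
        self.intro_tally = np.zeros(len(registry), dtype=np.int64)

    @property
    def alien_indices(self) -> np.ndarray:
        return np.arange(self.n_native, len(self.registry))

    def total_individuals(self) -> int:
        return sum(len(p.individuals) for p in self.island)

    def extant_species_indices(self) -> np.ndarray:
        present = [np.unique(p.individuals.species) for p in self.island if len(p.individuals)]
        if not present:
            return np.empty(0, dtype=np.int32)
        return np.unique(np.concatenate(present))

    def native_richness(self) -> int:
        return int((self.extant_species_indices() < self.n_native).sum())


def initialize_world(config: ScenarioConfig) -> WorldState:
    """Generate species pools and found the native island community.

    Native founders are placed as adults in every patch where the species
    mean adaptation reaches the establishment threshold, with per-patch
    founder count ``floor(founder_fill * capacity / adult_mass)``. The alien
    pool is generated (from the same trait-generation process) but not
    placed. Pool generation and founder noise draw from ``pool_seed``;
    the yearly dynamics from ``rng_seed``, so scenarios sharing a pool seed
    start from identical communities.
    """
    island = build_island(config.side, config.base_temperature, config.precip_range, config.entry_cell)
    ranges = config.trait_ranges or TraitRanges.for_island(
        island.realized_temperature_range, config.precip_range
    )
    pool_seed = config.rng_seed if config.pool_seed is None else config.pool_seed
    pool_rng = np.random.default_rng(pool_seed)
    arch = default_architecture()
    natives = [
        random_species(pool_rng, ranges, Origin.NATIVE_POOL, f"N{i:03d}", arch)
        for i in range(config.n_native_pool)
    ]
    aliens = [
        random_species(pool_rng, ranges, Origin.ALIEN_POOL, f"A{i:03d}", arch)
        for i in range(config.n_alien_pool)
    ]
    registry = natives + aliens
    means = np.stack([sp.mean_traits.as_array() for sp in registry])
    world = WorldState(config, island, registry, means, len(natives),
                       np.random.default_rng(config.rng_seed))

    placed = 0
    for patch in island:
        patch.individuals = Population.empty(arch)
        batches = []
        for si, sp in enumerate(natives):
            aind = dem.adaptation(sp.mean_traits, patch).combined
            if aind < config.establishment_threshold:
                continue
            count = int(np.floor(config.founder_fill * patch.capacity / sp.mean_traits.adult_mass))
            if count < 1:
                continue
            alleles = founder_alleles(
                np.repeat(means[si][None, :], count, axis=0), pool_rng, config.trait_cv, arch
            )
            phen = express_trait_matrix(alleles, arch)
            batches.append(
                Population(
                    ids=world.ids.take(count),
                    species=np.full(count, si, dtype=np.int32),
                    alleles=alleles,
                    phen=phen,
                    mass=phen[:, ADULT_MASS].copy(),
                    introduced=np.zeros(count, dtype=bool),
                    architecture=arch,
                )
            )
        for b in batches:
            patch.individuals = patch.individuals.extend(b)
            placed += len(b)
        patch.individuals.ensure_adaptation(patch.temperature, patch.precipitation)
    if placed == 0:
        raise ConfigurationError(
            "no native species could establish anywhere on the island; "
            "try another rng_seed or widen the trait-generation ranges"
        )
    return world


def run_year(world: WorldState, after_competition=None) -> WorldState:
    """Advance the world by one year, applying the processes in fixed order:
    survival, growth, competition, reproduction, then (after burn-in)
    disturbance and transport, then seed dispersal.

    ``after_competition`` is an optional observer called with the world right
    after the competition phase (the point where the biomass-capacity
    invariant holds by construction).
    """
    cfg = world.config
    island = world.island
    rng = world.rng
    year = world.year + 1

    for patch in island:
        dem.survival_step(patch, cfg.mte, rng, collect_removed=False)
    for patch in island:
        dem.growth_step(patch, cfg.mte)
    for patch in island:
        dem.competition_step(patch, rng, collect_removed=False)
    if after_competition is not None:
        after_competition(world)
    seed_batches = [
        (patch.row, patch.col, dem.reproduction_step(patch, cfg.mte, rng, world.ids))
        for patch in island
    ]
    if year > cfg.burn_in:
        for patch in island:
            dem.disturbance_step(patch, cfg.disturbance, rng, collect_removed=False)
        _, drawn = dem.transport_step(
            island,
            world.means[world.n_native:],
            world.alien_indices,
            cfg.propagule_pressure,
            rng,
            year=year,
            burn_in=cfg.burn_in,
            cv=cfg.trait_cv,
            threshold=cfg.establishment_threshold,
            architecture=world.registry[0].architecture if world.registry else default_architecture(),
            ids=world.ids,
            bernoulli=cfg.bernoulli_establishment,
        )
        np.add.at(world.intro_tally, world.alien_indices[drawn], 1)
    dem.dispersal_step(
        island, seed_batches, rng, cfg.establishment_threshold, cfg.bernoulli_establishment
    )
    for patch in island:
        patch.individuals.compact_pool()
    world.year = year
    return world


# ---------------------------------------------------------------------------
# census and map logging

CENSUS_COLUMNS = (
    ["year", "base_temperature", "propagule_pressure", "disturbance", "replicate",
     "species", "origin", "row", "col", "abundance"]
    + [f"med_{n}" for n in TRAIT_NAMES]
    + [f"var_{n}" for n in TRAIT_NAMES]
    + ["median_aind"]
)


def census_rows(world: WorldState) -> List[dict]:
    """One row per extant population (species x patch): abundance, trait
    medians and variances (population variance, ddof=0), median adaptation."""
    cfg = world.config
    rows: List[dict] = []
    for patch in world.island:
        pop: Population = patch.individuals
        if len(pop) == 0:
            continue
        a_t, a_p = pop.ensure_adaptation(patch.temperature, patch.precipitation)
        aind = a_t * a_p
        order = np.argsort(pop.species, kind="stable")
        sp_sorted = pop.species[order]
        uniq, starts = np.unique(sp_sorted, return_index=True)
        bounds = np.append(starts, len(sp_sorted))
        for u, s, e in zip(uniq, bounds[:-1], bounds[1:]):
            idx = order[s:e]
            phen = pop.phen[idx]
            sp = world.registry[int(u)]
            row = {
                "year": world.year,
                "base_temperature": cfg.base_temperature,
                "propagule_pressure": cfg.propagule_pressure,
                "disturbance": cfg.disturbance,
                "replicate": cfg.replicate_id,
                "species": sp.species_id,
                "origin": sp.origin.value,
                "row": patch.row,
                "col": patch.col,
                "abundance": int(e - s),
            }
            med = np.median(phen, axis=0)
            var = phen.var(axis=0)
            for t, name in enumerate(TRAIT_NAMES):
                row[f"med_{name}"] = med[t]
                row[f"var_{name}"] = var[t]
            row["median_aind"] = float(np.median(aind[idx]))
            rows.append(row)
    return rows


def map_rows(world: WorldState) -> List[dict]:
    """Island-map snapshot: one row per population with its abundance."""
    rows = []
    for patch in world.island:
        pop: Population = patch.individuals
        if len(pop) == 0:
            continue
        uniq, counts = np.unique(pop.species, return_counts=True)
        for u, c in zip(uniq, counts):
            sp = world.registry[int(u)]
            rows.append(
                {
                    "year": world.year,
                    "row": patch.row,
                    "col": patch.col,
                    "species": sp.species_id,
                    "origin": sp.origin.value,
                    "abundance": int(c),
                }
            )
    return rows


@dataclass
class RunResult:
    """Outputs of one scenario run."""

    config: ScenarioConfig
    census: pd.DataFrame
    maps: pd.DataFrame
    world: Optional[WorldState] = None

    @property
    def final_census(self) -> pd.DataFrame:
        if len(self.census) == 0:
            return self.census
        return self.census[self.census["year"] == self.census["year"].max()]


def _write_tsv(df: pd.DataFrame, path: Path, header_lines: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format=CENSUS_FLOAT_FORMAT)


def run_scenario(config: ScenarioConfig, out_dir: Optional[Path] = None) -> RunResult:
    """Run one scenario to its horizon, recording censuses and map snapshots.

    Censuses are taken at year 0 and every ``census_interval`` years; island
    maps at the end of burn-in and at the horizon. With ``out_dir`` set, the
    census, map and species-pool tables are written as TSV (with the island
    geometry and resolved constants echoed as comment lines).
    """
    world = initialize_world(config)
    census: List[dict] = census_rows(world)
    maps: List[dict] = []
    if config.burn_in == 0:
        maps.extend(map_rows(world))
    for _ in range(config.horizon):
        run_year(world)
        if world.year % config.census_interval == 0:
            census.extend(census_rows(world))
        if world.year in (config.burn_in, config.horizon):
            maps.extend(map_rows(world))
    census_df = pd.DataFrame(census, columns=CENSUS_COLUMNS)
    maps_df = pd.DataFrame(maps, columns=["year", "row", "col", "species", "origin", "abundance"])
    result = RunResult(config=config, census=census_df, maps=maps_df, world=world)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        header = world.island.geometry_header() + config.resolved_constants_header()
        _write_tsv(census_df, out_dir / "census.tsv", header)
        _write_tsv(maps_df, out_dir / "map.tsv", header)
        _write_tsv(species_pool_table(world), out_dir / "species_pool.tsv", header)
    return result


def species_pool_table(world: WorldState) -> pd.DataFrame:
    """Species pools as a table (id, origin, the eight mean traits)."""
    rows = []
    for sp in world.registry:
        row = {"species": sp.species_id, "origin": sp.origin.value}
        row.update({n: getattr(sp.mean_traits, n) for n in TRAIT_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full-factorial experiment


def derive_seeds(base_seed: int, replicate: int, scenario_index: int) -> Tuple[int, int]:
    """Stable (dynamics_seed, pool_seed) for one run of the experiment.

    The pool seed depends only on (base_seed, replicate), so every scenario
    shares species pools with its paired replicate in the other factor
    levels; the dynamics seed additionally mixes in the scenario index.
    Both are reduced below 2**31.
    """
    pool = int(np.random.SeedSequence([base_seed, replicate, 10_000_019]).generate_state(1)[0] % (2**31))
    dyn = int(np.random.SeedSequence([base_seed, replicate, scenario_index]).generate_state(1)[0] % (2**31))
    return dyn, pool


def scenario_grid(
    temperature_levels: Sequence[float] = (15.0, 35.0),
    propagule_levels: Sequence[int] = (1, 10),
    disturbance_levels: Sequence[float] = (0.01, 0.10),
) -> List[Tuple[float, int, float]]:
    """The factor grid in deterministic order (temperature, pressure, disturbance)."""
    return [
        (t, p, d)
        for t in temperature_levels
        for p in propagule_levels
        for d in disturbance_levels
    ]


def full_experiment(
    base_config: ScenarioConfig,
    replicates: int,
    base_seed: int = 0,
    temperature_levels: Sequence[float] = (15.0, 35.0),
    propagule_levels: Sequence[int] = (1, 10),
    disturbance_levels: Sequence[float] = (0.01, 0.10),
    out_dir: Optional[Path] = None,
    independent_pools: bool = False,
    progress: bool = False,
) -> Tuple[pd.DataFrame, List[RunResult]]:
    """Run the full-factorial design (2 x 2 x 2 by default) with replicates.

    Returns (manifest, results). The manifest holds one row per run with its
    factor levels, seeds and (if written) output directory. With
    ``independent_pools`` the species pools are regenerated per run instead
    of being shared across factor levels within a replicate.
    """
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    grid = scenario_grid(temperature_levels, propagule_levels, disturbance_levels)
    manifest_rows = []
    results: List[RunResult] = []
    for rep in range(replicates):
        for s_idx, (temp, pressure, dist) in enumerate(grid):
            dyn_seed, pool_seed = derive_seeds(base_seed, rep, s_idx)
            if independent_pools:
                pool_seed = dyn_seed
            cfg = dataclasses.replace(
                base_config,
                base_temperature=temp,
                propagule_pressure=pressure,
                disturbance=dist,
                replicate_id=rep,
                rng_seed=dyn_seed,
                pool_seed=pool_seed,
            )
            run_dir = None
            if out_dir is not None:
                run_dir = Path(out_dir) / f"s{s_idx}_r{rep}"
            result = run_scenario(cfg, out_dir=run_dir)
            results.append(result)
            manifest_rows.append(
                {
                    "scenario_index": s_idx,
                    "base_temperature": temp,
                    "propagule_pressure": pressure,
                    "disturbance": dist,
                    "replicate": rep,
                    "rng_seed": dyn_seed,
                    "pool_seed": pool_seed,
                    "side": cfg.side,
                    "burn_in": cfg.burn_in,
                    "horizon": cfg.horizon,
                    "n_native_pool": cfg.n_native_pool,
                    "n_alien_pool": cfg.n_alien_pool,
                    "census_interval": cfg.census_interval,
                    "run_dir": str(run_dir) if run_dir is not None else "",
                }
            )
            if progress:  # pragma: no cover - cosmetic
                print(f"run s{s_idx} r{rep} done: year {result.world.year}")
    manifest = pd.DataFrame(manifest_rows)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        manifest.to_csv(Path(out_dir) / "manifest.tsv", sep="\t", index=False)
    return manifest, results
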