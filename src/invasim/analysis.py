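"""Species categorization, invasion counts, and the exported trait table.

At the end of a run each extant species is assigned exactly one category:

* **native** — a species from the original island community still extant;
* **alien** — an introduced species whose populations never left the point
  of entry;
* **invasive** — an introduced species with at least one population outside
  the point of entry (landscape spread).

Introduced species that died out entirely appear in a separate "failed"
tally (colonization-pressure bookkeeping), not as a category.

For trait comparisons between categories, populations from the final census
of every run are pooled into a tidy table of log(x+1)-transformed trait
medians (niche optima are excluded: they track geography and the temperature
scenario rather than invasiveness). That table is the input to standard
statistical tooling (mixed models, pairwise tests, PCA); this package's
contract ends at the table.
"""

from __future__ import annotations

import enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .demography import gauss
from .landscape import Island, build_island
from .simulation import RunResult


class SpeciesCategory(enum.Enum):
    NATIVE = "native"
    ALIEN = "alien"
    INVASIVE = "invasive"


#: trait-table columns (log1p of final-census population medians)
TRAIT_TABLE_TRAITS = (
    "dispersal_scale",
    "dispersal_shape",
    "precip_tolerance",
    "temp_tolerance",
    "adult_mass",
    "seed_mass",
)


def categorize_species(
    final_census: pd.DataFrame, entry_cell: Tuple[int, int]
) -> Dict[str, SpeciesCategory]:
    """Map each extant species at the final census to its category.

    ``final_census`` must carry ``species``, ``origin``, ``row``, ``col``
    columns (one row per population). Extinct species receive no category.
    """
    out: Dict[str, SpeciesCategory] = {}
    er, ec = entry_cell
    for species, grp in final_census.groupby("species", sort=True):
        origin = grp["origin"].iloc[0]
        if origin == "native":
            out[str(species)] = SpeciesCategory.NATIVE
        else:
            outside = ((grp["row"] != er) | (grp["col"] != ec)).any()
            out[str(species)] = SpeciesCategory.INVASIVE if outside else SpeciesCategory.ALIEN
    return out


def failed_introductions(result: RunResult) -> List[str]:
    """Introduced species that arrived at least once but are extinct at the end."""
    world = result.world
    extant = {world.registry[int(i)].species_id for i in world.extant_species_indices()}
    out = []
    for idx in world.alien_indices:
        if world.intro_tally[idx] > 0 and world.registry[int(idx)].species_id not in extant:
            out.append(world.registry[int(idx)].species_id)
    return out


def _entry_cell(result: RunResult) -> Tuple[int, int]:
    if result.world is not None:
        entry = result.world.island.entry_patch
        return entry.row, entry.col
    cfg = result.config
    return cfg.entry_cell if cfg.entry_cell is not None else ((cfg.side - 1) // 2, 0)


def run_categories(result: RunResult) -> Dict[str, SpeciesCategory]:
    return categorize_species(result.final_census, _entry_cell(result))


def category_timeseries(result: RunResult) -> pd.DataFrame:
    """Category of every extant species at every census year (extra output)."""
    rows = []
    entry = _entry_cell(result)
    for year, grp in result.census.groupby("year", sort=True):
        for species, cat in categorize_species(grp, entry).items():
            rows.append({"year": year, "species": species, "category": cat.value})
    return pd.DataFrame(rows, columns=["year", "species", "category"])


def invasion_counts(
    runs: Iterable[RunResult],
    factor_levels: Optional[Sequence[Tuple[float, int, float]]] = None,
) -> pd.DataFrame:
    """Cumulative invasive-species count per scenario, summed over replicates.

    Each run contributes the number of species categorized invasive at its
    final census; a species invading in two replicates counts twice. Returns
    one row per scenario (all scenarios present, zeros included when
    ``factor_levels`` supplies the grid).
    """
    rows = []
    for result in runs:
        cats = run_categories(result)
        n_inv = sum(1 for c in cats.values() if c is SpeciesCategory.INVASIVE)
        cfg = result.config
        rows.append(
            {
                "base_temperature": cfg.base_temperature,
                "propagule_pressure": cfg.propagule_pressure,
                "disturbance": cfg.disturbance,
                "n_invasive": n_inv,
                "n_runs": 1,
            }
        )
    df = pd.DataFrame(rows)
    keys = ["base_temperature", "propagule_pressure", "disturbance"]
    if len(df) == 0:
        agg = pd.DataFrame(columns=keys + ["n_invasive", "n_runs"])
    else:
        agg = df.groupby(keys, as_index=False).sum()
    if factor_levels is not None:
        grid = pd.DataFrame(factor_levels, columns=keys)
        agg = grid.merge(agg, on=keys, how="left").fillna({"n_invasive": 0, "n_runs": 0})
        agg[["n_invasive", "n_runs"]] = agg[["n_invasive", "n_runs"]].astype(int)
    return agg


def population_adaptation(census_row: pd.Series, island: Island) -> float:
    """Combined adaptation of a population: the Gaussian-niche product
    evaluated at the population's trait medians against its own patch."""
    patch = island.patch(int(census_row["row"]), int(census_row["col"]))
    a_t = gauss(census_row["med_temp_optimum"], census_row["med_temp_tolerance"], patch.temperature)
    a_p = gauss(
        census_row["med_precip_optimum"], census_row["med_precip_tolerance"], patch.precipitation
    )
    return float(a_t * a_p)


def _island_for(result: RunResult) -> Island:
    cfg = result.config
    return build_island(cfg.side, cfg.base_temperature, cfg.precip_range, cfg.entry_cell)


def export_trait_table(runs: Iterable[RunResult]) -> pd.DataFrame:
    """Pooled per-population trait table from the final census of every run.

    One row per population (species x patch): category, scenario labels,
    replicate, patch, abundance, and log(x+1)-transformed medians of the six
    analyzed traits plus the population adaptation. This is the tidy input
    for downstream mixed models / pairwise tests / PCA.
    """
    rows = []
    for result in runs:
        cfg = result.config
        island = _island_for(result)
        cats = run_categories(result)
        for _, crow in result.final_census.iterrows():
            cat = cats[str(crow["species"])]
            aind = population_adaptation(crow, island)
            row = {
                "category": cat.value,
                "base_temperature": cfg.base_temperature,
                "propagule_pressure": cfg.propagule_pressure,
                "disturbance": cfg.disturbance,
                "replicate": cfg.replicate_id,
                "rng_seed": cfg.rng_seed,
                "species": crow["species"],
                "row": int(crow["row"]),
                "col": int(crow["col"]),
                "abundance": int(crow["abundance"]),
            }
            for name in TRAIT_TABLE_TRAITS:
                row[f"log1p_{name}"] = float(np.log1p(crow[f"med_{name}"]))
            row["log1p_aind"] = float(np.log1p(aind))
            rows.append(row)
    cols = (
        ["category", "base_temperature", "propagule_pressure", "disturbance", "replicate",
         "rng_seed", "species", "row", "col", "abundance"]
        + [f"log1p_{n}" for n in TRAIT_TABLE_TRAITS]
        + ["log1p_aind"]
    )
    return pd.DataFrame(rows, columns=cols)


def category_medians(trait_table: pd.DataFrame) -> pd.DataFrame:
    """Median of each log1p column per species category (summary helper)."""
    value_cols = [c for c in trait_table.columns if c.startswith("log1p_")]
    return trait_table.groupby("category")[value_cols].median()
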