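"""Gridded island landscape: radial temperature gradient, linear precipitation gradient.

The island is a square grid of one-hectare patches. Elevation rises in
concentric rings toward the center cell (Chebyshev-distance rings), and
temperature drops by a fixed lapse step per unit of height, producing a radial
temperature gradient around a central "mountain". A second, abstract
environmental gradient (called precipitation) varies linearly across columns,
as on oceanic islands lying in the path of prevailing winds. A single fixed
edge cell is the point of entry for all introduced propagules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Tuple

import numpy as np

#: biomass carrying capacity of one patch, in grams (two tonnes per hectare)
PATCH_CAPACITY_G = 2_000_000.0

#: temperature decrease per unit of elevation, in degrees Celsius
LAPSE_PER_HEIGHT_C = 2.0


class _OffIsland:
    """Sentinel for coordinates beyond the island borders (seeds there die)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "OFF_ISLAND"

    def __bool__(self) -> bool:
        return False


OFF_ISLAND = _OffIsland()


class ConfigurationError(ValueError):
    """Raised for invalid landscape or scenario configuration."""


@dataclass
class Patch:
    """One 1-ha grid cell with its local environment and resident plants.

    ``individuals`` is whatever population container the caller attaches
    (the simulator uses an array-backed :class:`~invasim.population.Population`);
    the landscape itself only owns the geometry and environment.
    """

    row: int
    col: int
    elevation: int
    temperature: float  # Tenv, degrees Celsius
    precipitation: float  # Penv, abstract units
    capacity: float = PATCH_CAPACITY_G
    is_entry: bool = False
    individuals: object = None

    @property
    def temperature_kelvin(self) -> float:
        return self.temperature + 273.15


@dataclass
class Island:
    """Square grid of patches with the two environmental gradients."""

    side: int
    base_temperature: float
    precip_range: Tuple[float, float]
    patches: list = field(default_factory=list)  # row-major list of rows

    def patch(self, row: int, col: int) -> Patch:
        return self.patches[row][col]

    def __iter__(self) -> Iterator[Patch]:
        for row in self.patches:
            yield from row

    @property
    def entry_patch(self) -> Patch:
        for p in self:
            if p.is_entry:
                return p
        raise ConfigurationError("island has no entry patch")

    @property
    def temperatures(self) -> np.ndarray:
        """(side, side) array of patch temperatures."""
        return np.array([[p.temperature for p in row] for row in self.patches])

    @property
    def realized_temperature_range(self) -> Tuple[float, float]:
        t = self.temperatures
        return float(t.min()), float(t.max())

    def geometry_header(self) -> list[str]:
        """TSV comment lines echoing the island geometry into run logs."""
        return [
            f"# island side={self.side}",
            f"# base_temperature={self.base_temperature}",
            f"# precip_range={self.precip_range[0]},{self.precip_range[1]}",
            f"# entry_cell={self.entry_patch.row},{self.entry_patch.col}",
            f"# patch_capacity_g={PATCH_CAPACITY_G}",
        ]


def build_island(
    side: int = 5,
    base_temperature: float = 15.0,
    precip_range: Tuple[float, float] = (0.0, 10.0),
    entry_cell: Tuple[int, int] | None = None,
) -> Island:
    """Construct the island grid.

    Elevation of a cell is its ring index counted from the outside in,
    ``(side-1)//2 - max(|row-c|, |col-c|)`` for center index ``c``: the edge
    ring sits at elevation 0 and the center cell at ``(side-1)//2``.
    Temperature is ``base_temperature - 2 * elevation``; precipitation is
    affine in the column index over ``precip_range``.

    Parameters
    ----------
    side:
        Odd grid side length >= 3 (default 5, i.e. a 5x5 island).
    base_temperature:
        Lowland (edge-ring) temperature in degrees Celsius.
    precip_range:
        (min, max) of the abstract precipitation gradient across columns.
    entry_cell:
        (row, col) of the point of entry; default is the mid-edge lowland
        cell ``((side-1)//2, 0)`` on the dry side.
    """
    if side < 3 or side % 2 == 0:
        raise ConfigurationError(f"island side must be odd and >= 3, got {side}")
    lo, hi = precip_range
    if not lo < hi:
        raise ConfigurationError(f"precip_range must satisfy min < max, got {precip_range}")
    if entry_cell is None:
        entry_cell = ((side - 1) // 2, 0)
    er, ec = entry_cell
    if not (0 <= er < side and 0 <= ec < side):
        raise ConfigurationError(f"entry_cell {entry_cell} outside {side}x{side} grid")

    center = (side - 1) // 2
    rows = []
    for r in range(side):
        row = []
        for c in range(side):
            elev = center - max(abs(r - center), abs(c - center))
            temp = base_temperature - LAPSE_PER_HEIGHT_C * elev
            precip = lo + c * (hi - lo) / (side - 1)
            row.append(
                Patch(
                    row=r,
                    col=c,
                    elevation=elev,
                    temperature=temp,
                    precipitation=precip,
                    is_entry=(r, c) == (er, ec),
                )
            )
        rows.append(row)
    return Island(side=side, base_temperature=base_temperature, precip_range=(lo, hi), patches=rows)


def patch_at(island: Island, x: float, y: float):
    """Map continuous coordinates to the containing patch, or ``OFF_ISLAND``.

    Patch centers sit at integer coordinates (x along columns, y along rows);
    each patch is the half-open unit square ``[c-0.5, c+0.5)``. Any point
    outside ``[-0.5, side-0.5)`` on either axis is off the island.
    """
    col = int(np.floor(x + 0.5))
    row = int(np.floor(y + 0.5))
    if 0 <= row < island.side and 0 <= col < island.side:
        return island.patch(row, col)
    return OFF_ISLAND


def patch_indices_at(island_side: int, x: np.ndarray, y: np.ndarray):
    """Vectorized :func:`patch_at`: returns (row, col, on_island_mask) arrays."""
    col = np.floor(x + 0.5).astype(np.int64)
    row = np.floor(y + 0.5).astype(np.int64)
    ok = (row >= 0) & (row < island_side) & (col >= 0) & (col < island_side)
    return row, col, ok
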