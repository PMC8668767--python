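"""Array-backed population container.

A :class:`Population` stores a group of plants (the residents of one patch,
or a transient batch such as a year's seed rain) as a structure of numpy
arrays, which is what makes whole-community simulation tractable: every
yearly process is a vectorized operation over these arrays.

Genomes are held in an :class:`AllelePool` — an append-only array of diploid
allele blocks — and each individual carries a 4-byte reference into it.
Allele blocks never change after creation (mutation is off), so the yearly
survival/competition/disturbance compactions copy only the references, not
the genomes; pools are compacted locally once dead rows dominate. Each
population references exactly one pool, and populations derived by
``subset`` share their parent's pool.

The container still behaves as a collection of
:class:`~invasim.genetics.Individual` — it has a length, can be iterated,
and materializes individual objects on demand — so code and tests can use
either view.
"""

from __future__ import annotations

from typing import Iterator, List, Sequence

import numpy as np

from .genetics import (
    Architecture,
    Genome,
    Individual,
    Species,
    TraitSet,
    default_architecture,
    express_trait_matrix,
)


class IdCounter:
    """Monotone allocator of unique individual ids for one simulation run."""

    __slots__ = ("next_id",)

    def __init__(self, start: int = 0):
        self.next_id = int(start)

    def take(self, n: int) -> np.ndarray:
        out = np.arange(self.next_id, self.next_id + n, dtype=np.int64)
        self.next_id += int(n)
        return out


class AllelePool:
    """Append-only store of diploid allele blocks, shape (capacity, 2, G)."""

    __slots__ = ("data", "n")

    def __init__(self, n_genes: int, dtype=np.float32, initial: np.ndarray | None = None):
        if initial is not None:
            self.data = np.ascontiguousarray(initial, dtype=dtype)
            self.n = initial.shape[0]
        else:
            self.data = np.empty((0, 2, n_genes), dtype=dtype)
            self.n = 0

    @property
    def n_genes(self) -> int:
        return self.data.shape[2]

    def append(self, blocks: np.ndarray) -> np.ndarray:
        """Append (k, 2, G) allele blocks; returns their int32 references."""
        k = blocks.shape[0]
        if self.n + k > self.data.shape[0]:
            new_cap = max(self.n + k, 2 * self.data.shape[0], 1024)
            grown = np.empty((new_cap, 2, self.n_genes), dtype=self.data.dtype)
            grown[: self.n] = self.data[: self.n]
            self.data = grown
        self.data[self.n : self.n + k] = blocks
        refs = np.arange(self.n, self.n + k, dtype=np.int32)
        self.n += k
        return refs

    def gather(self, refs: np.ndarray) -> np.ndarray:
        """Allele blocks for the given references, shape (len(refs), 2, G)."""
        return np.take(self.data[: self.n], refs, axis=0)


class Population:
    """Structure-of-arrays collection of individuals.

    Attributes
    ----------
    ids : (N,) int64 — unique individual ids.
    species : (N,) int32 — indices into the run's species registry.
    pool / refs : genome storage; ``alleles`` gathers the (N, 2, G) view.
    phen : (N, 8) float — expressed (clamped) phenotypes; cached because
        mutation is off and alleles never change after creation.
    mass : (N,) float — current mass in grams.
    introduced : (N,) bool — True for transported propagules themselves
        (descent from introductions is tracked through species origin).
    a_t, a_p : cached niche-adaptation columns against one patch
        environment, valid while ``adapt_env`` matches that patch's (T, P).
    """

    __slots__ = ("ids", "species", "pool", "refs", "phen", "mass", "introduced",
                 "architecture", "a_t", "a_p", "adapt_env")

    #: storage dtype for allele/phenotype/mass arrays; single precision is
    #: ample for simulated trait values and halves the memory traffic of the
    #: per-year compaction passes.
    DTYPE = np.float32

    def __init__(self, ids, species, alleles=None, phen=None, mass=None, introduced=None,
                 architecture=None, pool=None, refs=None, a_t=None, a_p=None, adapt_env=None):
        self.ids = np.asarray(ids, dtype=np.int64)
        self.species = np.asarray(species, dtype=np.int32)
        self.architecture = architecture or default_architecture()
        if pool is not None:
            self.pool = pool
            self.refs = np.asarray(refs, dtype=np.int32)
        else:
            blocks = np.asarray(alleles, dtype=self.DTYPE)
            self.pool = AllelePool(self.architecture.n_genes, self.DTYPE, initial=blocks)
            self.refs = np.arange(blocks.shape[0], dtype=np.int32)
        self.phen = np.asarray(phen, dtype=self.DTYPE)
        self.mass = np.asarray(mass, dtype=self.DTYPE)
        self.introduced = np.asarray(introduced, dtype=bool)
        n = self.ids.shape[0]
        self.a_t = np.zeros(n, self.DTYPE) if a_t is None else np.asarray(a_t, self.DTYPE)
        self.a_p = np.zeros(n, self.DTYPE) if a_p is None else np.asarray(a_p, self.DTYPE)
        self.adapt_env = adapt_env

    @property
    def alleles(self) -> np.ndarray:
        """(N, 2, G) allele array (gathered copy from the pool)."""
        return self.pool.gather(self.refs)

    def ensure_adaptation(self, temperature: float, precipitation: float):
        """(A_T, A_P) of every individual against the given environment.

        Phenotypes are immutable and plants do not move between patches, so
        the columns are cached and only recomputed when the environment key
        changes (e.g. for a population newly built from individuals).
        """
        key = (float(temperature), float(precipitation))
        if self.adapt_env != key:
            from .genetics import POPT, PTOL, TOPT, TTOL

            p = self.phen
            dt = (key[0] - p[:, TOPT]) / p[:, TTOL]
            dp = (key[1] - p[:, POPT]) / p[:, PTOL]
            self.a_t = np.exp(-0.5 * dt * dt)
            self.a_p = np.exp(-0.5 * dp * dp)
            self.adapt_env = key
        return self.a_t, self.a_p

    # -- construction -------------------------------------------------------

    @classmethod
    def empty(cls, architecture: Architecture | None = None) -> "Population":
        arch = architecture or default_architecture()
        g = arch.n_genes
        return cls(
            ids=np.empty(0, dtype=np.int64),
            species=np.empty(0, dtype=np.int32),
            alleles=np.empty((0, 2, g)),
            phen=np.empty((0, 8)),
            mass=np.empty(0),
            introduced=np.empty(0, dtype=bool),
            architecture=arch,
        )

    @classmethod
    def from_arrays(cls, ids, species, alleles, mass, introduced, architecture=None) -> "Population":
        arch = architecture or default_architecture()
        phen = express_trait_matrix(np.asarray(alleles, dtype=cls.DTYPE), arch)
        return cls(ids, species, alleles, phen, mass, introduced, arch)

    @classmethod
    def from_individuals(
        cls, individuals: Sequence[Individual], registry: Sequence[Species]
    ) -> "Population":
        """Build the array view from Individual objects (registry maps ids)."""
        arch = individuals[0].genome.architecture if individuals else default_architecture()
        index = {sp.species_id: i for i, sp in enumerate(registry)}
        ids = [ind.id for ind in individuals]
        species = [index[ind.species_id] for ind in individuals]
        alleles = (
            np.stack([ind.genome.alleles for ind in individuals])
            if individuals
            else np.empty((0, 2, arch.n_genes))
        )
        mass = [ind.mass for ind in individuals]
        introduced = [ind.introduced for ind in individuals]
        return cls.from_arrays(ids, species, alleles, mass, introduced, arch)

    # -- collection protocol ------------------------------------------------

    def __len__(self) -> int:
        return int(self.ids.shape[0])

    def individual(self, i: int, registry: Sequence[Species], location=(0, 0)) -> Individual:
        sp = registry[self.species[i]]
        return Individual(
            id=int(self.ids[i]),
            species_id=sp.species_id,
            genome=Genome(
                alleles=np.array(self.pool.data[self.refs[i]], dtype=float),
                architecture=self.architecture,
            ),
            phenotype=TraitSet.from_array(self.phen[i]),
            mass=float(self.mass[i]),
            location=tuple(location),
            introduced=bool(self.introduced[i]),
        )

    def to_individuals(self, registry: Sequence[Species], location=(0, 0)) -> List[Individual]:
        return [self.individual(i, registry, location) for i in range(len(self))]

    def __iter__(self) -> Iterator[int]:
        return iter(range(len(self)))

    # -- manipulation -------------------------------------------------------

    def subset(self, mask_or_index) -> "Population":
        idx = mask_or_index
        if np.asarray(idx).dtype == bool:
            idx = np.flatnonzero(idx)
        return Population(
            np.take(self.ids, idx),
            np.take(self.species, idx),
            phen=np.take(self.phen, idx, axis=0),
            mass=np.take(self.mass, idx),
            introduced=np.take(self.introduced, idx),
            architecture=self.architecture,
            pool=self.pool,
            refs=np.take(self.refs, idx),
            a_t=np.take(self.a_t, idx),
            a_p=np.take(self.a_p, idx),
            adapt_env=self.adapt_env,
        )

    def split(self, keep_mask: np.ndarray) -> tuple["Population", "Population"]:
        """Return (kept, removed) populations."""
        return self.subset(keep_mask), self.subset(~keep_mask)

    def extend(self, other: "Population") -> "Population":
        """Concatenated population; the other's genomes join this one's pool."""
        if len(other) == 0:
            return self
        if len(self) == 0:
            return other
        new_refs = self.pool.append(other.pool.gather(other.refs))
        same_env = self.adapt_env is not None and self.adapt_env == other.adapt_env
        return Population(
            np.concatenate([self.ids, other.ids]),
            np.concatenate([self.species, other.species]),
            phen=np.concatenate([self.phen, other.phen]),
            mass=np.concatenate([self.mass, other.mass]),
            introduced=np.concatenate([self.introduced, other.introduced]),
            architecture=self.architecture,
            pool=self.pool,
            refs=np.concatenate([self.refs, new_refs]),
            a_t=np.concatenate([self.a_t, other.a_t]) if same_env else None,
            a_p=np.concatenate([self.a_p, other.a_p]) if same_env else None,
            adapt_env=self.adapt_env if same_env else None,
        )

    def compact_pool(self, slack: int = 4) -> None:
        """Drop dead genome rows once they dominate the pool.

        Rebuilds a fresh pool holding only this population's live blocks when
        the pool has grown beyond ``slack`` times the population size. Other
        populations still referencing the old pool object are unaffected.
        """
        if self.pool.n > max(1024, slack * len(self)):
            live = self.pool.gather(self.refs)
            self.pool = AllelePool(self.architecture.n_genes, self.DTYPE, initial=live)
            self.refs = np.arange(live.shape[0], dtype=np.int32)

    @property
    def biomass(self) -> float:
        return float(self.mass.sum(dtype=np.float64))
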