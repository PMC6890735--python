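"""Spawner allocation, pairing, density-dependent fecundity and inheritance.

Adults lack natal homing: spawning-run adults choose tributaries in
proportion to the larval abundance already present (a pheromone cue), so a
tributary holding a fraction ``l_i / sum(l)`` of all larvae receives, in
expectation, that fraction of the spawning run.  An alternative linear
stepping-stone mode sends each adult home with probability ``1 - m`` and to
an adjacent tributary with probability ``m`` (split evenly; edge tributaries
send all migrants to their single neighbour).

Within a tributary, females and males are paired at random and every pair
produces the same number of offspring,

    N_offspring = K_t / (0.5 * N_t) * n_m + n_a,

where ``K_t`` is the tributary's carrying capacity, ``N_t`` the adults
assigned there, and ``n_m``/``n_a`` tune density-dependent vs
density-independent output (variance among pairs arises later through
recruit mortality).  Resistance is a single-locus dominant trait; each
offspring inherits one uniformly chosen allele from each parent.  A
fecundity cost multiplies the pair's output by ``(1 - cost)`` once per
phenotypically resistant parent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import FEMALE, MALE, Pool
from .parameters import GrowthParams

__all__ = [
    "SpawnerAllocation",
    "Pairing",
    "allocate_spawners_no_homing",
    "allocate_spawners_stepping_stone",
    "form_pairs",
    "offspring_per_pair",
    "apply_resistance_cost",
    "make_offspring",
    "is_resistant",
]


def is_resistant(alleles):
    """Dominant phenotype: resistant iff carrying at least one allele."""
    if np.isscalar(alleles):
        return alleles >= 1
    return np.asarray(alleles) >= 1


@dataclass
class SpawnerAllocation:
    """Assignment of staged adults to spawning tributaries."""

    destination: np.ndarray  # tributary index per staged adult
    counts: np.ndarray       # adults per tributary

    def __post_init__(self) -> None:
        assert int(self.counts.sum()) == self.destination.shape[0]


def _allocation_from_destinations(dest: np.ndarray, n_tributaries: int) -> SpawnerAllocation:
    counts = np.bincount(dest, minlength=n_tributaries).astype(np.int64)
    return SpawnerAllocation(destination=dest, counts=counts)


def allocate_spawners_no_homing(
    larval_counts: np.ndarray,
    n_adults: int,
    rng: np.random.Generator,
) -> SpawnerAllocation:
    """Assign each adult independently to tributary i w.p. l_i / sum(l).

    A multinomial realisation of the abundance-proportional expectation;
    natal origin is ignored.  If no tributary holds larvae the run is spread
    uniformly (documented fallback for an edge case the life history leaves
    undefined).
    """
    weights = np.asarray(larval_counts, dtype=np.float64)
    n_trib = weights.shape[0]
    total = weights.sum()
    if total > 0:
        p = weights / total
    else:
        p = np.full(n_trib, 1.0 / n_trib)
    dest = rng.choice(n_trib, size=int(n_adults), p=p)
    return _allocation_from_destinations(dest, n_trib)


def allocate_spawners_stepping_stone(
    natal: np.ndarray,
    gene_flow: float,
    n_tributaries: int,
    rng: np.random.Generator,
) -> SpawnerAllocation:
    """Linear stepping-stone spawning: stay home w.p. 1-m, else step +/-1.

    Interior migrants split evenly between the two neighbours; tributaries at
    the ends of the line reflect their whole migrant mass onto their single
    neighbour.
    """
    if not 0.0 <= gene_flow <= 1.0:
        raise ValueError("gene_flow must lie in [0, 1]")
    natal = np.asarray(natal, dtype=np.int64)
    n = natal.shape[0]
    dest = natal.copy()
    if n and gene_flow > 0 and n_tributaries > 1:
        migrate = rng.random(n) < gene_flow
        step = rng.integers(0, 2, n) * 2 - 1
        dest[migrate] += step[migrate]
        dest[dest < 0] = 1
        dest[dest > n_tributaries - 1] = n_tributaries - 2
    return _allocation_from_destinations(dest, n_tributaries)


@dataclass
class Pairing:
    """Monogamous random pairing within one tributary's spawning run."""

    females: np.ndarray   # indices into the adult pool, one per pair
    males: np.ndarray     # indices into the adult pool, aligned with females
    unpaired: np.ndarray  # indices of leftover adults (excess sex)

    @property
    def n_pairs(self) -> int:
        return self.females.shape[0]


def form_pairs(adults: Pool, rng: np.random.Generator) -> Pairing:
    """Shuffle each sex independently and zip into min(#F, #M) pairs."""
    idx_f = np.flatnonzero(adults.sex == FEMALE)
    idx_m = np.flatnonzero(adults.sex == MALE)
    rng.shuffle(idx_f)
    rng.shuffle(idx_m)
    n = min(idx_f.shape[0], idx_m.shape[0])
    unpaired = np.concatenate([idx_f[n:], idx_m[n:]])
    return Pairing(females=idx_f[:n], males=idx_m[:n], unpaired=unpaired)


def offspring_per_pair(K_t: float, N_t: int, n_m: float, n_a: float) -> int:
    """Per-pair offspring count before recruit mortality (0 if N_t < 2).

    Rounded to the nearest integer, ties to even.
    """
    if N_t < 2:
        return 0
    return int(round(K_t / (N_t * 0.5) * n_m + n_a))


def apply_resistance_cost(
    n_offspring: int,
    mother_alleles: int,
    father_alleles: int,
    cost: float,
    mode: str = "per_parent",
) -> int:
    """Reduce a pair's offspring count for resistant parentage.

    ``per_parent`` (default) multiplies by ``(1-cost)`` once per resistant
    parent (two resistant parents compound); ``max_parent`` applies the
    penalty at most once.  Result rounded to nearest, ties to even.
    """
    if not 0.0 <= cost <= 1.0:
        raise ValueError("cost must lie in [0, 1]")
    r = int(is_resistant(mother_alleles)) + int(is_resistant(father_alleles))
    if mode == "max_parent":
        r = min(r, 1)
    elif mode != "per_parent":
        raise ValueError(f"unknown cost mode {mode!r}")
    return int(round(n_offspring * (1.0 - cost) ** r))


def mendelian_alleles(
    mother_alleles: int,
    father_alleles: int,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw offspring allele counts: one uniform allele from each parent."""
    a = (rng.random(n) < mother_alleles / 2.0).astype(np.int8)
    a += rng.random(n) < father_alleles / 2.0
    return a


def make_offspring(
    mother_alleles: int,
    father_alleles: int,
    n: int,
    tributary: int,
    rng: np.random.Generator,
    growth: GrowthParams,
) -> Pool:
    """Create ``n`` newborn larvae for one pair in ``tributary``.

    Each offspring inherits one randomly selected allele from each parent,
    receives a fresh lifetime growth coefficient, a 50:50 random sex, age 0
    and natal tributary equal to its birth tributary.
    """
    from .demography import draw_growth_parameter  # local import avoids cycle noise

    n = int(n)
    if n < 0:
        raise ValueError("offspring count must be non-negative")
    alleles = mendelian_alleles(mother_alleles, father_alleles, n, rng)
    return Pool(
        age_days=np.zeros(n, np.int32),
        k=np.atleast_1d(draw_growth_parameter(rng, growth, size=n)),
        alleles=alleles,
        sex=rng.integers(0, 2, n).astype(np.int8),
        natal=np.full(n, tributary, np.int32),
    )
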