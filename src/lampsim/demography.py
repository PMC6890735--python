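"""Individuals, Von Bertalanffy growth, and size-triggered stage transitions.

Lamprey pass through three stages: stream-dwelling larvae (ammocoetes),
lake-dwelling parasitic juveniles, and semelparous adults.  Body length
follows the Von Bertalanffy curve

    L(t) = L_inf * (1 - exp(-k * (t - t0)))

with one age clock per individual (days since birth) and a stage-specific
asymptotic length ``L_inf`` (150 mm for larvae, 800 mm for juveniles).  A
larva metamorphoses when its larval-scale length reaches 120 mm; a juvenile
matures when its juvenile-scale length reaches 450 mm.  Because the length
ratio 120/150 maps to 640 mm on the juvenile scale, every juvenile is past
the maturation threshold one year after transformation — the model's
"typically one year in the lake" life history.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.special import ndtr, ndtri

from .parameters import GrowthParams, ModelParams

__all__ = [
    "FEMALE",
    "MALE",
    "LAKE",
    "Individual",
    "Pool",
    "SystemState",
    "draw_growth_parameter",
    "body_length",
    "transformation_age_days",
    "advance_ages",
    "transform_larvae",
    "mature_juveniles",
]

FEMALE, MALE = 0, 1
#: Sentinel location index for the lake (juveniles live outside tributaries).
LAKE = -1

DAYS_PER_YEAR = 365


@dataclass
class Individual:
    """Record-level view of one lamprey (used for I/O and small-scale tests).

    The simulation engine itself stores populations column-wise in
    :class:`Pool`; ``Individual`` is the one-row counterpart.
    """

    id: int
    sex: int
    age_days: int
    k: float
    stage: str  # "larva" | "juvenile" | "adult"
    n_resistance_alleles: int
    natal_tributary: int
    location: int  # tributary index, or LAKE for juveniles

    def __post_init__(self) -> None:
        if self.n_resistance_alleles not in (0, 1, 2):
            raise ValueError("n_resistance_alleles must be 0, 1 or 2")
        if self.k <= 0:
            raise ValueError("growth parameter k must be positive")
        if self.stage == "juvenile" and self.location != LAKE:
            raise ValueError("juveniles live in the lake")
        if self.stage == "larva" and self.location < 0:
            raise ValueError("larvae live in a tributary")


class Pool:
    """Column-wise container for a group of individuals sharing a stage.

    Columns: ``age_days`` (int32), ``k`` (float64, per-day growth
    coefficient), ``alleles`` (int8 resistance-allele count), ``sex`` (int8),
    ``natal`` (int32 natal-tributary index).
    """

    __slots__ = ("age_days", "k", "alleles", "sex", "natal")

    def __init__(self, age_days, k, alleles, sex, natal):
        self.age_days = np.asarray(age_days, dtype=np.int32)
        self.k = np.asarray(k, dtype=np.float64)
        self.alleles = np.asarray(alleles, dtype=np.int8)
        self.sex = np.asarray(sex, dtype=np.int8)
        self.natal = np.asarray(natal, dtype=np.int32)

    @classmethod
    def empty(cls) -> "Pool":
        return cls(
            np.empty(0, np.int32), np.empty(0, np.float64),
            np.empty(0, np.int8), np.empty(0, np.int8), np.empty(0, np.int32),
        )

    def __len__(self) -> int:
        return self.age_days.shape[0]

    def take(self, index) -> "Pool":
        """Subset by boolean mask or integer index array."""
        return Pool(self.age_days[index], self.k[index], self.alleles[index],
                    self.sex[index], self.natal[index])

    @staticmethod
    def concat(pools: Sequence["Pool"]) -> "Pool":
        pools = [p for p in pools if len(p)]
        if not pools:
            return Pool.empty()
        if len(pools) == 1:
            return pools[0]
        return Pool(
            np.concatenate([p.age_days for p in pools]),
            np.concatenate([p.k for p in pools]),
            np.concatenate([p.alleles for p in pools]),
            np.concatenate([p.sex for p in pools]),
            np.concatenate([p.natal for p in pools]),
        )

    @classmethod
    def from_individuals(cls, individuals: Iterable[Individual]) -> "Pool":
        rows = list(individuals)
        return cls(
            [i.age_days for i in rows], [i.k for i in rows],
            [i.n_resistance_alleles for i in rows], [i.sex for i in rows],
            [i.natal_tributary for i in rows],
        )

    def to_individuals(self, stage: str, location: int, start_id: int = 0) -> list[Individual]:
        return [
            Individual(start_id + i, int(self.sex[i]), int(self.age_days[i]),
                       float(self.k[i]), stage, int(self.alleles[i]),
                       int(self.natal[i]), location)
            for i in range(len(self))
        ]


@dataclass
class SystemState:
    """Full population state: larval tributaries, lake pool, staged adults.

    ``fresh_juveniles`` counts lake entries appended by the current year's
    transformation step; they are excluded from the same year's maturation
    check so that maturation occurs at the earliest one year after
    metamorphosis.
    """

    year: int
    tributaries: list[Pool]
    lake: Pool
    adults_staged: Pool = field(default_factory=Pool.empty)
    fresh_juveniles: int = 0

    @property
    def n_tributaries(self) -> int:
        return len(self.tributaries)

    def larval_counts(self) -> np.ndarray:
        return np.array([len(p) for p in self.tributaries], dtype=np.int64)

    def resistant_larval_counts(self) -> np.ndarray:
        return np.array(
            [int((p.alleles >= 1).sum()) for p in self.tributaries], dtype=np.int64
        )

    def total_individuals(self) -> int:
        return int(self.larval_counts().sum()) + len(self.lake) + len(self.adults_staged)


def draw_growth_parameter(
    rng: np.random.Generator,
    growth: GrowthParams,
    size: Optional[int] = None,
    transform_length_mm: float = 120.0,
) -> Union[float, np.ndarray]:
    """Draw lifelong growth coefficient(s) ``k``.

    Draws come from N(k_mean, k_sd^2); when the growth model specifies a
    transformation-age window, the draw is restricted (by inverse-CDF
    truncation, equivalent to resampling) to coefficients whose larval curve
    crosses ``transform_length_mm`` inside that window.  Without a window,
    non-positive draws are resampled.  A degenerate spread returns the mean
    exactly.
    """
    n = 1 if size is None else int(size)
    sd = growth.k_sd
    if sd == 0.0:
        out = np.full(n, growth.k_mean)
        return float(out[0]) if size is None else out

    if growth.transform_window_years is not None:
        lo_y, hi_y = growth.transform_window_years
        # k such that transformation age == a: k = log(Linf/(Linf-L)) / (a*365 - t0)
        log_ratio = np.log(growth.L_inf_larva / (growth.L_inf_larva - transform_length_mm))
        k_hi = log_ratio / (lo_y * DAYS_PER_YEAR - growth.t0)
        k_lo = log_ratio / (hi_y * DAYS_PER_YEAR - growth.t0)
        p_lo = ndtr((k_lo - growth.k_mean) / sd)
        p_hi = ndtr((k_hi - growth.k_mean) / sd)
        u = rng.uniform(p_lo, p_hi, n)
        out = growth.k_mean + sd * ndtri(u)
    else:
        out = rng.normal(growth.k_mean, sd, n)
        bad = out <= 0
        while bad.any():
            out[bad] = rng.normal(growth.k_mean, sd, int(bad.sum()))
            bad = out <= 0
    out = np.maximum(out, growth.k_floor)
    return float(out[0]) if size is None else out


def body_length(k, age_days, L_inf: float, t0: float):
    """Von Bertalanffy length (mm) at age ``age_days`` (vectorised)."""
    k = np.asarray(k, dtype=np.float64)
    age = np.asarray(age_days, dtype=np.float64)
    return L_inf * (1.0 - np.exp(-k * (age - t0)))


def transformation_age_days(k, growth: GrowthParams, threshold_mm: float = 120.0):
    """Age (days) at which the larval curve crosses ``threshold_mm``."""
    k = np.asarray(k, dtype=np.float64)
    ratio = growth.L_inf_larva / (growth.L_inf_larva - threshold_mm)
    return growth.t0 + np.log(ratio) / k


def advance_ages(state: SystemState) -> SystemState:
    """Age every individual by one year (in place; returns the state)."""
    for pool in state.tributaries:
        pool.age_days += DAYS_PER_YEAR
    state.lake.age_days += DAYS_PER_YEAR
    state.adults_staged.age_days += DAYS_PER_YEAR
    return state


def transform_larvae(state: SystemState, params: ModelParams) -> SystemState:
    """Move every larva at/above the 120-mm larval length into the lake.

    New juveniles are appended to the lake pool and counted in
    ``state.fresh_juveniles`` so the same-year maturation pass skips them.
    """
    g = params.growth
    # L(t) >= threshold  <=>  k*(t - t0) >= log(L_inf / (L_inf - threshold))
    log_ratio = np.log(g.L_inf_larva / (g.L_inf_larva - params.transform_length_mm))
    moved: list[Pool] = []
    for t, pool in enumerate(state.tributaries):
        if not len(pool):
            continue
        mask = pool.k * (pool.age_days - g.t0) >= log_ratio
        if mask.any():
            moved.append(pool.take(mask))
            state.tributaries[t] = pool.take(~mask)
    if moved:
        n_new = sum(len(p) for p in moved)
        state.lake = Pool.concat([state.lake] + moved)
        state.fresh_juveniles += n_new
    return state


def mature_juveniles(state: SystemState, params: ModelParams) -> SystemState:
    """Stage every eligible juvenile (juvenile-scale length >= 450 mm) as an adult.

    Juveniles that transformed earlier in the same yearly pass (tracked via
    ``fresh_juveniles``) are not eligible; everyone else is checked against
    the juvenile growth curve.
    """
    g = params.growth
    lake = state.lake
    n_old = len(lake) - state.fresh_juveniles
    if n_old <= 0:
        state.fresh_juveniles = 0
        return state
    old = lake.take(slice(0, n_old))
    fresh = lake.take(slice(n_old, len(lake)))
    log_ratio = np.log(g.L_inf_juvenile / (g.L_inf_juvenile - params.mature_length_mm))
    mask = old.k * (old.age_days - g.t0) >= log_ratio
    if mask.all():
        # common case: every juvenile that survived a lake year is past 450 mm
        state.adults_staged = Pool.concat([state.adults_staged, old])
        state.lake = fresh
    else:
        state.adults_staged = Pool.concat([state.adults_staged, old.take(mask)])
        state.lake = Pool.concat([old.take(~mask), fresh])
    state.fresh_juveniles = 0
    return state
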