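"""Annual scheduler, replicate execution and reproducible seeding.

One model year runs, in order: ageing -> metamorphosis of larvae at the
120-mm threshold -> maturation of lake juveniles (plus the one-off
introduction of a heterozygous resistant adult in the scheduled year) ->
allocation of the spawning run to tributaries -> pairing and reproduction
with the fecundity cost -> removal of all adults (semelparity) -> natural
larval mortality -> TFM treatment of the selected tributaries -> natural
juvenile mortality in the lake.  The first 50 years serve as burn-in during
which the age and stage structure equilibrates before treatment begins.

Reproduction and recruit mortality are executed as one exact-distribution
step: per-pair offspring counts are computed first, the carrying-capacity
cull draws the surviving recruits by a multivariate hypergeometric split
across pairs, and only survivors are instantiated (with Mendelian genotypes,
sexes and growth coefficients).  This is sample-for-sample equivalent to
creating every offspring and culling uniformly, without materialising the
~K*n_m newborns per tributary each year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .demography import (
    Pool,
    SystemState,
    advance_ages,
    draw_growth_parameter,
    mature_juveniles,
    transform_larvae,
)
from .mortality import natural_mortality, plan_treatment, apply_tfm, survivor_target
from .parameters import ModelParams
from .reproduction import (
    allocate_spawners_no_homing,
    allocate_spawners_stepping_stone,
    offspring_per_pair,
)

__all__ = [
    "Trajectory",
    "initialize_population",
    "introduce_resistant_adult",
    "run_year",
    "run_simulation",
    "run_replicates",
]

SeedLike = Union[None, int, np.random.SeedSequence, np.random.Generator]


@dataclass
class Trajectory:
    """Per-year observer record for one replicate."""

    n_years: int
    n_tributaries: int
    seed: Optional[int] = None
    parasites: np.ndarray = field(init=False)        # juveniles at transformation census
    lake_size: np.ndarray = field(init=False)        # lake pool after juvenile mortality
    adults: np.ndarray = field(init=False)           # spawning-run size
    larvae_total: np.ndarray = field(init=False)     # end-of-year larvae
    resistant_larvae: np.ndarray = field(init=False)
    trib_larvae: np.ndarray = field(init=False)      # (year, tributary)
    trib_resistant: np.ndarray = field(init=False)
    treated: np.ndarray = field(init=False)          # bool mask (year, tributary)
    tfm_killed: np.ndarray = field(init=False)
    recruits: np.ndarray = field(init=False)         # surviving first-year larvae
    deaths_natural: np.ndarray = field(init=False)   # recruit + standing + lake culls

    def __post_init__(self) -> None:
        n, t = self.n_years, self.n_tributaries
        for name in ("parasites", "lake_size", "adults", "larvae_total",
                     "resistant_larvae", "tfm_killed", "recruits", "deaths_natural"):
            setattr(self, name, np.zeros(n, dtype=np.int64))
        self.trib_larvae = np.zeros((n, t), dtype=np.int32)
        self.trib_resistant = np.zeros((n, t), dtype=np.int32)
        self.treated = np.zeros((n, t), dtype=bool)

    @property
    def years(self) -> np.ndarray:
        return np.arange(1, self.n_years + 1)

    def resistant_fraction(self) -> np.ndarray:
        """Resistant larvae as a fraction of all larvae (0 where empty)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.resistant_larvae / self.larvae_total
        return np.where(self.larvae_total > 0, f, 0.0)

    def spread(self) -> np.ndarray:
        """Per-year fraction of tributaries holding >= 1 resistant larva."""
        return (self.trib_resistant > 0).mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Year-level metrics as a tidy table."""
        return pd.DataFrame({
            "year": self.years,
            "parasitic_juveniles": self.parasites,
            "lake_after_mortality": self.lake_size,
            "adults": self.adults,
            "larvae_total": self.larvae_total,
            "resistant_larvae": self.resistant_larvae,
            "resistant_fraction": self.resistant_fraction(),
            "spread_fraction": self.spread(),
            "treated_tributaries": self.treated.sum(axis=1),
            "tfm_killed": self.tfm_killed,
            "recruits": self.recruits,
            "deaths_natural": self.deaths_natural,
        })

    def tributary_frame(self) -> pd.DataFrame:
        """Per-tributary counts in long format."""
        n, t = self.trib_larvae.shape
        return pd.DataFrame({
            "year": np.repeat(self.years, t),
            "tributary": np.tile(np.arange(t), n),
            "larvae": self.trib_larvae.ravel(),
            "resistant_larvae": self.trib_resistant.ravel(),
            "treated": self.treated.ravel(),
        })


def _rng_from(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def initialize_population(params: ModelParams, rng: np.random.Generator) -> SystemState:
    """Seed each tributary with ``larval_K`` larvae and the lake with
    ``juvenile_K`` juveniles; sexes 50:50, ages spread across the stage
    windows, and no resistance alleles anywhere."""
    g = params.growth
    tribs: list[Pool] = []
    for t in range(params.n_tributaries):
        n = params.larval_K
        tribs.append(Pool(
            age_days=(rng.integers(0, 7, n) * 365).astype(np.int32),
            k=np.atleast_1d(draw_growth_parameter(rng, g, size=n,
                                                  transform_length_mm=params.transform_length_mm)),
            alleles=np.zeros(n, np.int8),
            sex=rng.integers(0, 2, n).astype(np.int8),
            natal=np.full(n, t, np.int32),
        ))
    n = params.juvenile_K
    lake = Pool(
        age_days=(rng.integers(4, 7, n) * 365).astype(np.int32),
        k=np.atleast_1d(draw_growth_parameter(rng, g, size=n,
                                              transform_length_mm=params.transform_length_mm)),
        alleles=np.zeros(n, np.int8),
        sex=rng.integers(0, 2, n).astype(np.int8),
        natal=rng.integers(0, params.n_tributaries, n).astype(np.int32),
    )
    return SystemState(year=0, tributaries=tribs, lake=lake)


def introduce_resistant_adult(
    state: SystemState, params: ModelParams, rng: np.random.Generator
) -> SystemState:
    """Append one heterozygous resistant adult to the staged spawning run.

    The founder has random sex and a random natal tributary; under the
    default no-homing life history it joins the abundance-proportional
    allocation like any other adult.
    """
    founder = Pool(
        age_days=np.array([6 * 365], np.int32),
        k=np.atleast_1d(draw_growth_parameter(rng, params.growth, size=1,
                                              transform_length_mm=params.transform_length_mm)),
        alleles=np.array([1], np.int8),
        sex=rng.integers(0, 2, 1).astype(np.int8),
        natal=rng.integers(0, params.n_tributaries, 1).astype(np.int32),
    )
    state.adults_staged = Pool.concat([state.adults_staged, founder])
    return state


def _reproduce_tributary(
    existing: Pool,
    adult_alleles: np.ndarray,
    adult_sex: np.ndarray,
    tributary: int,
    params: ModelParams,
    rng: np.random.Generator,
) -> tuple[Pool, np.ndarray, np.ndarray, int]:
    """One tributary's reproduction + larval natural mortality.

    Returns (surviving standing pool, surviving recruits' maternal and
    paternal allele counts, natural deaths among standing larvae); recruit
    individuals themselves are instantiated in one batch by the caller.
    Equivalent to instantiating every pair's offspring and applying the
    uniform carrying-capacity cull; survivors are sampled directly via a
    multivariate hypergeometric split across pairs.
    """
    g = params.growth
    n_t = adult_alleles.shape[0]
    base = offspring_per_pair(params.larval_K, n_t, params.dd_weight, params.di_offset)
    pair_counts = np.empty(0, np.int64)
    gm = gf = np.empty(0, np.int8)
    if base > 0:
        # random monogamous pairing: shuffle each sex's genotypes and zip
        gm = adult_alleles[adult_sex == 0]
        gf = adult_alleles[adult_sex == 1]
        n_pairs = min(gm.shape[0], gf.shape[0])
        if n_pairs:
            rng.shuffle(gm)
            rng.shuffle(gf)
            gm, gf = gm[:n_pairs], gf[:n_pairs]
            if params.resistance_cost > 0:
                r = (gm >= 1).astype(np.int64) + (gf >= 1)
                pair_counts = np.rint(
                    base * (1.0 - params.resistance_cost) ** (
                        np.minimum(r, 1) if params.cost_mode == "max_parent" else r)
                ).astype(np.int64)
            else:
                pair_counts = np.full(n_pairs, base, dtype=np.int64)
        else:
            gm = gf = np.empty(0, np.int8)

    m_total = int(pair_counts.sum())
    e = len(existing)
    standing_deaths = 0
    if params.larval_mortality_scope == "pool":
        # Spec-literal variant: the cull draws uniformly from standing larvae
        # and newborns together.
        target = survivor_target(params.larval_K, params.mortality_sd, e + m_total, rng)
        n_exist = rng.hypergeometric(e, m_total, target) if (e and target < e + m_total) \
            else min(e, target)
        if n_exist < e:
            existing = existing.take(rng.permutation(e)[:n_exist])
            standing_deaths = e - n_exist
        n_recruits = target - n_exist
    else:
        # Default: the deviate sets first-year survival of the newborn cohort;
        # standing larvae are not subject to the density-regulating cull.
        n_recruits = survivor_target(params.larval_K, params.mortality_sd, m_total, rng)

    if n_recruits <= 0 or m_total == 0:
        return existing, np.empty(0, np.int8), np.empty(0, np.int8), standing_deaths

    surv = rng.multivariate_hypergeometric(pair_counts, n_recruits)
    return existing, np.repeat(gm, surv), np.repeat(gf, surv), standing_deaths


def run_year(
    state: SystemState,
    params: ModelParams,
    rng: np.random.Generator,
    traj: Optional[Trajectory] = None,
) -> SystemState:
    """Advance the system by one model year (see module docstring for order)."""
    state.year += 1
    y = state.year - 1  # trajectory row index

    advance_ages(state)
    transform_larvae(state, params)
    mature_juveniles(state, params)
    parasites_census = len(state.lake)

    if state.year == params.resistant_intro_year:
        introduce_resistant_adult(state, params, rng)

    adults = state.adults_staged
    n_adults = len(adults)
    recruits_total = 0
    natural_deaths = 0
    pool_scope = params.larval_mortality_scope == "pool"
    if n_adults:
        counts = state.larval_counts()
        if params.migration_mode == "no_homing":
            alloc = allocate_spawners_no_homing(counts, n_adults, rng)
        else:
            alloc = allocate_spawners_stepping_stone(
                adults.natal, params.gene_flow, params.n_tributaries, rng)
        order = np.argsort(alloc.destination, kind="stable")
        dest_sorted = alloc.destination[order]
        alleles_sorted = adults.alleles[order]
        sex_sorted = adults.sex[order]
        bounds = np.searchsorted(dest_sorted, np.arange(params.n_tributaries + 1))
        per_trib_gm: list[np.ndarray] = []
        per_trib_gf: list[np.ndarray] = []
        trib_ids: list[int] = []
        for t in range(params.n_tributaries):
            sl = slice(bounds[t], bounds[t + 1])
            if bounds[t + 1] - bounds[t] < 2 and not pool_scope:
                continue
            pool, gm_c, gf_c, n_dead = _reproduce_tributary(
                state.tributaries[t], alleles_sorted[sl], sex_sorted[sl],
                t, params, rng)
            state.tributaries[t] = pool
            natural_deaths += n_dead
            if gm_c.shape[0]:
                per_trib_gm.append(gm_c)
                per_trib_gf.append(gf_c)
                trib_ids.append(t)
        if trib_ids:
            # batch-instantiate all surviving recruits of the year at once
            sizes = [a.shape[0] for a in per_trib_gm]
            gm_all = np.concatenate(per_trib_gm)
            gf_all = np.concatenate(per_trib_gf)
            n_all = gm_all.shape[0]
            recruits_total = n_all
            alleles = (rng.random(n_all) < gm_all / 2.0).astype(np.int8)
            alleles += rng.random(n_all) < gf_all / 2.0
            k_all = np.atleast_1d(draw_growth_parameter(
                rng, params.growth, size=n_all,
                transform_length_mm=params.transform_length_mm))
            sex_all = rng.integers(0, 2, n_all).astype(np.int8)
            age_all = np.zeros(n_all, np.int32)
            offsets = np.cumsum([0] + sizes)
            for j, t in enumerate(trib_ids):
                sl = slice(offsets[j], offsets[j + 1])
                recruits = Pool(age_all[sl], k_all[sl], alleles[sl], sex_all[sl],
                                np.full(sizes[j], t, np.int32))
                state.tributaries[t] = Pool.concat([state.tributaries[t], recruits])
    elif pool_scope:
        for t in range(params.n_tributaries):
            before = len(state.tributaries[t])
            state.tributaries[t] = natural_mortality(
                state.tributaries[t], params.larval_K, params.mortality_sd, rng)
            natural_deaths += before - len(state.tributaries[t])

    # Semelparity: the entire spawning run dies after reproduction.
    state.adults_staged = Pool.empty()

    plan = plan_treatment(state, params, rng)
    killed_total = 0
    for t in plan.treated:
        pool, killed = apply_tfm(state.tributaries[t], params.tfm_mortality, rng)
        state.tributaries[t] = pool
        killed_total += killed

    lake_before = len(state.lake)
    state.lake = natural_mortality(
        state.lake, params.juvenile_K, params.effective_juvenile_sd, rng)
    natural_deaths += lake_before - len(state.lake)

    if traj is not None:
        traj.parasites[y] = parasites_census
        traj.lake_size[y] = len(state.lake)
        traj.adults[y] = n_adults
        counts = state.larval_counts()
        res = state.resistant_larval_counts()
        traj.trib_larvae[y] = counts
        traj.trib_resistant[y] = res
        traj.larvae_total[y] = counts.sum()
        traj.resistant_larvae[y] = res.sum()
        traj.treated[y, plan.treated] = True
        traj.tfm_killed[y] = killed_total
        traj.recruits[y] = recruits_total
        traj.deaths_natural[y] = natural_deaths
    return state


def run_simulation(params: ModelParams, seed: SeedLike = None) -> Trajectory:
    """Run one replicate for ``params.n_years`` from a fresh population."""
    if seed is None:
        seed = params.seed
    rng = _rng_from(seed)
    state = initialize_population(params, rng)
    traj = Trajectory(params.n_years, params.n_tributaries,
                      seed=seed if isinstance(seed, int) else None)
    for _ in range(params.n_years):
        run_year(state, params, rng, traj)
    return traj


def run_replicates(
    params: ModelParams,
    n_replicates: int,
    base_seed: Optional[int] = None,
) -> list[Trajectory]:
    """Run independent replicates with child seeds spawned from ``base_seed``.

    Child streams are derived with :class:`numpy.random.SeedSequence`, so each
    replicate is reproducible in isolation and replicate order is immaterial.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if base_seed is None:
        base_seed = params.seed
    root = np.random.SeedSequence(base_seed)
    return [run_simulation(params, child) for child in root.spawn(n_replicates)]
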