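"""Density-regulating natural mortality and annual TFM treatment.

Natural mortality is a carrying-capacity cull: the number of survivors is a
normal deviate centred on the capacity (sd 70 by default), rounded, clamped
to the pool size, with survivors drawn uniformly at random — blind to
resistance status.  The same operation regulates the first-year larval
cohort in each tributary and the lake-wide juvenile pool.

TFM treatment selects a fixed number of tributaries each year.  Larval
abundance surveys prioritise the largest populations, so the default policy
treats the top-ranked tributaries by larval head count (ties broken by
tributary index); probabilistic priority ("weighted") and uniform rotation
are available as policy variants.  Within a treated tributary each
susceptible (zero-allele) larva dies independently with the TFM mortality
probability; resistant larvae always survive treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .demography import Pool, SystemState
from .parameters import ModelParams

__all__ = [
    "TreatmentPlan",
    "natural_mortality",
    "survivor_target",
    "plan_treatment",
    "apply_tfm",
    "treatment_scheduled",
]


def survivor_target(K: float, sd: float, pool_size: int, rng: np.random.Generator) -> int:
    """Rounded normal deviate around the capacity, clamped to [0, pool_size]."""
    draw = rng.normal(K, sd) if sd > 0 else float(K)
    return int(np.clip(np.rint(draw), 0, pool_size))


def natural_mortality(pool: Pool, K: float, sd: float, rng: np.random.Generator) -> Pool:
    """Cull a pool back toward its carrying capacity.

    Survivors are chosen uniformly at random, irrespective of genotype, sex
    or age.  A pool already at/below the drawn target is untouched.
    """
    n = len(pool)
    target = survivor_target(K, sd, n, rng)
    if target >= n:
        return pool
    keep = rng.permutation(n)[:target]
    return pool.take(keep)


def treatment_scheduled(year: int, params: ModelParams) -> bool:
    """True when TFM is applied in ``year`` (start inclusive, stop exclusive)."""
    if year < params.tfm_start_year:
        return False
    if params.tfm_stop_year is not None and year >= params.tfm_stop_year:
        return False
    return True


@dataclass
class TreatmentPlan:
    """Which tributaries receive TFM this year."""

    year: int
    treated: np.ndarray  # tributary indices
    larval_counts: np.ndarray  # survey counts the plan was based on

    @property
    def treated_count(self) -> int:
        return self.treated.shape[0]


def plan_treatment(
    state: SystemState,
    params: ModelParams,
    rng: Optional[np.random.Generator] = None,
) -> TreatmentPlan:
    """Select the tributaries to treat this year.

    Outside the treatment schedule, or with a zero treated count, the plan is
    empty.  Under the default ``rank`` priority the ``treated_count`` largest
    larval populations are chosen deterministically (ties broken by lowest
    tributary index).  ``weighted`` samples without replacement with
    probability proportional to larval count; ``uniform`` rotates at random.
    The stochastic policies require ``rng``.
    """
    counts = state.larval_counts()
    k = params.treated_count
    if k <= 0 or not treatment_scheduled(state.year, params):
        return TreatmentPlan(state.year, np.empty(0, np.int64), counts)
    k = min(k, params.n_tributaries)
    if params.treatment_priority == "rank":
        order = np.lexsort((np.arange(counts.shape[0]), -counts))
        treated = order[:k]
    else:
        if rng is None:
            raise ValueError(
                f"treatment priority {params.treatment_priority!r} needs an rng"
            )
        if params.treatment_priority == "weighted":
            total = counts.sum()
            p = counts / total if total > 0 else None
            treated = rng.choice(counts.shape[0], size=k, replace=False, p=p)
        else:  # uniform
            treated = rng.choice(counts.shape[0], size=k, replace=False)
    return TreatmentPlan(state.year, np.sort(treated), counts)


def apply_tfm(
    pool: Pool,
    tfm_mortality: float,
    rng: np.random.Generator,
) -> tuple[Pool, int]:
    """Expose one tributary's larvae to TFM.

    Each susceptible larva dies independently with probability
    ``tfm_mortality``; resistant larvae (>= 1 allele) are unaffected.
    Returns the surviving pool and the kill count.
    """
    if not 0.0 <= tfm_mortality <= 1.0:
        raise ValueError("tfm_mortality must lie in [0, 1]")
    n = len(pool)
    if n == 0:
        return pool, 0
    die = (pool.alleles == 0) & (rng.random(n) < tfm_mortality)
    killed = int(die.sum())
    if killed == 0:
        return pool, 0
    return pool.take(~die), killed
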