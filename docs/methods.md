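# Model and methods

`lampsim` is a forward-time, individual-based eco-genetic model of invasive
sea lamprey (*Petromyzon marinus*) under annual control with the lampricide
TFM (3-trifluoromethyl-4-nitrophenol).  It couples a stage-structured life
history (stream larvae → lake-dwelling parasitic juveniles → semelparous
adults) with single-locus inheritance of a dominant resistance allele, and
asks how quickly resistance can establish, spread and — under a fitness
cost — be purged.

## Life cycle and annual schedule

One model year executes, in order:

1. **Ageing** — every individual gains 365 days.
2. **Metamorphosis** — a larva whose Von Bertalanffy length
   `L(t) = L∞·(1 − e^(−k(t − t0)))` (larval `L∞` = 150 mm, `t0` = −15 d)
   reaches 120 mm becomes a parasitic juvenile and moves to the single
   lake-wide pool.
3. **Maturation** — a juvenile whose juvenile-scale curve (`L∞` = 800 mm,
   same birth-anchored age clock) reaches 450 mm is staged for spawning.
   Because a fresh transformer is already at ≥(120/150)·800 = 640 mm on the
   juvenile scale, every juvenile that survives one lake year matures the
   next spring: maturation is effectively one year after metamorphosis.
   Same-year maturation of fresh transformers is excluded to preserve that
   timing.  In the introduction year (default 70), one heterozygous
   resistant adult of random sex joins the staged spawning run.
4. **Spawning-run allocation** — sea lamprey lack natal homing; adults
   choose streams by larval pheromone concentration.  Each adult is
   independently assigned to tributary *i* with probability
   `l_i / Σ l_i` (multinomial realisation of the abundance-proportional
   expectation).  The alternative *linear stepping-stone* mode sends each
   adult to its natal tributary with probability `1 − m` and to an adjacent
   one with probability `m` (even split; reflecting edges).
5. **Reproduction** — within a tributary, females and males are shuffled
   and paired monogamously; every pair produces
   `N_offspring = K_t/(0.5·N_t)·n_m + n_a` offspring (identical across
   pairs; variance enters through recruit mortality).  With the defaults
   (`n_m` = 50, `n_a` = 0) the tributary's newborn output is `K·n_m`
   regardless of spawner numbers — strongly compensatory density
   dependence.  Offspring inherit one uniformly chosen allele from each
   parent; resistance is dominant.  A fecundity cost multiplies a pair's
   output by `(1 − c)` once per resistant parent.  All adults then die
   (strict semelparity).
6. **Larval natural mortality** — the density-regulating cull.  A normal
   deviate with mean `K` (1200) and sd 70 sets the number of surviving
   *first-year recruits* in each tributary; survivors are drawn uniformly
   from the newborn cohort, blind to genotype and sex.  Standing larvae are
   not subject to this cull (they die only through treatment, and leave
   through metamorphosis).  See "Design choices" for why.
7. **TFM treatment** — from year 50 (until an optional stop year), a fixed
   number of tributaries (`round(treated_fraction × n_tributaries)`) is
   treated.  The default policy treats the top-ranked tributaries by larval
   head count (ties to the lower index), mirroring survey-driven
   prioritisation; probability-proportional and uniform-rotation policies
   are available.  In a treated tributary each susceptible larva dies
   independently with probability 0.9; resistant larvae always survive.
8. **Juvenile natural mortality** — the identical cull applied to the lake
   pool with the lake-wide capacity (8000, sd 70).

The first 50 years are burn-in; parasite production is stationary well
before treatment begins (tested).

## Growth-coefficient dispersion

Each individual keeps a lifelong growth coefficient `k` drawn from a normal
distribution with mean 0.001 d⁻¹.  The nominal dispersion figure 0.0002 is
read as a **variance** (sd ≈ 0.0141) — far wider than any biologically
possible growth rate — so draws are restricted, by inverse-CDF truncation,
to coefficients whose larval curve crosses 120 mm between ages 2 and 7
years (`k` ∈ (6.33·10⁻⁴, 2.19·10⁻³)).  Because the sd is ~9× the window
width, `k` is nearly uniform on the window; metamorphosis ages average
~3.5 y and the generation time is ~4.5 y.  Two alternatives are exposed on
`GrowthParams`: reading 0.0002 as an sd (`spread_is="sd"`), and disabling
the window (`transform_window_years=None`, positive draws only).  The
windowed-variance default is the only reading we found that reproduces the
full set of published ensemble statistics simultaneously (timing, detection
growth and establishment probability); the sd reading stretches the
generation to ~6.3 y and slows resistance dynamics by ~40%.

## Design choices in the mortality step

Three readings of "a normal deviate around K determines the surviving
larvae" were prototyped:

* *pool-wide uniform cull* — newborns (≈`K·n_m` = 60,000 per tributary)
  outnumber standing larvae ~50:1, so uniform survival leaves standing
  larvae ~2%/yr survival; nothing reaches 120 mm and the population
  collapses.  Retained as `larval_mortality_scope="pool"` for reference.
* *total-stock cull protecting recruits proportionally* — stationary, but
  couples recruitment to standing stock (`recruits ≈ K − standing`), which
  lets compensation absorb most of the TFM selection differential;
  resistance establishment collapses to ~1/4 of the published value.
* *first-year recruit cull* (default) — the deviate sets egg-to-recruit
  survival; this is also the step that introduces variance in per-pair
  offspring numbers.  It keeps the age structure, expresses the full
  selection differential, and reproduces the published statistics.

The parasite abundance series records juveniles at the
transformation/maturation census (entering the lake), before the lake cull;
the post-cull lake size is recorded separately.  At burn-in ~24,000
juveniles enter a lake capped at 8,000, so the pre-cull census is the only
series in which proportional treatment effects are not clipped by the cap.

## Numerical and implementation notes

* Rounding of offspring counts and cost-adjusted counts: nearest integer,
  ties to even.  Survivor targets: rounded normal deviate clamped to
  `[0, pool size]`.
* Reproduction and recruit mortality are fused: per-pair offspring counts
  are computed, the cull's survivors are allocated across pairs by a
  multivariate hypergeometric draw, and only survivors are instantiated
  (genotypes, sexes, growth coefficients).  This is sample-for-sample
  equivalent to creating all ~1.2 M newborns per year and culling uniformly
  (tested against the composed individual-level operations) and is what
  makes 100-replicate ensembles run in minutes on one core.
* Truncated-normal draws use the inverse CDF (`scipy.special.ndtri`);
  rejection sampling would accept only ~4% of draws under the default
  window.
* Seeding: one root seed per ensemble; replicate streams are spawned with
  `numpy.random.SeedSequence`, so any single replicate is reproducible in
  isolation and replicate order is immaterial.  Identical seeds give
  bit-identical trajectories.
* Degenerate inputs: an empty system is a fixed point of the annual cycle;
  a tributary with fewer than two adults (or a single sex) produces no
  offspring; an all-zero larval landscape spreads the spawning run
  uniformly.

## Observers

* **Development criterion**: >90% of all larvae resistant (strict), scored
  in the final year; time-to-resistance is the first crossing year minus
  the introduction year, reported among developing replicates.
* **Treatment efficacy**: 1 − (mean parasite census, years 60–69)/(mean,
  years 40–49), averaged over replicates.
* **Spread**: two statistics — instantaneous occupancy (fraction of
  tributaries with ≥1 resistant larva now) and colonisation
  (`tributaries_reached`: fraction ever holding one by a given year).  The
  acceptance analysis reports colonisation, since larval broods transform
  out of a tributary within a few years and instantaneous occupancy
  systematically undercounts how far a lineage has spread.  Ensemble
  curves average over replicates whose lineage is alive that year.
* **Detection**: repeated simple random samples (default 500) of a fixed
  fraction of the pooled larval population, drawn without replacement
  (hypergeometric), scored for containing ≥1 resistant larva, assuming
  perfect identification.  Agrees with the closed form
  `1 − (1−p)^n` at these population sizes (tested).

## What the simulations do and do not show

The model is a deliberately small caricature of the Great Lakes system
(20 tributaries of 1200 larvae; real larval populations number in the tens
of millions).  Frequencies, proportions and timing generalise across scale
— treatment efficacy is unchanged under a tenfold capacity scaling (tested)
— but the *absolute* delay before a single founder's lineage crosses a
frequency threshold grows logarithmically with population size, so
times-to-resistance at management scale would shift by roughly
`ln(scale)/r` years.  Not modelled: sub-annual dynamics, prey/host
feedbacks, length-dependent fecundity, imperfect resistance phenotyping,
partial-stream treatment, TFM dose-response, and polygenic resistance
architectures (a single dominant locus is assumed throughout).

## Problem sizes used in checks

The test suite runs reduced ensembles (30–50 replicates; the capacity-
scaling check uses 10 tenfold-scaled replicates) and downsized systems for
property tests; `scripts/acceptance.py` runs the full 100-replicate study
design for every reported statistic (the 5%-gene-flow spread ensemble runs
100 years, as its statistic is read 15 years post-introduction).
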