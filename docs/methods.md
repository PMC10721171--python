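# Methods

This note documents the model implemented by `pestevol`, the conventions
and defaults it adopts where the design was genuinely open, and what the
bundled tests do and do not demonstrate.

## Genotype→phenotype networks

An individual's genotype is a row vector of `L` locus values; its `T`
traits are produced by multiplying that vector through an `L×T` matrix
(locus effects on the first layer of internal nodes) and then `layers`
successive `T×T` matrices (transitions between internal layers, the last
of which yields the traits).  All link weights are unconstrained reals.
Because the map is linear, the composite `L×T` matrix `M` fully determines
the trait distribution: for loci ~ N(0, I), traits are multivariate normal
with covariance `MᵀM` (`expected_covariance`).  Trait means are added
separately via `trait_means`, so the network controls (co)variances only.

Flattened genome order is: loci, then the `L×T` block row-major, then each
`T×T` layer map row-major.  Network files are plain text: a header line
`L T layers` followed by the flattened network values.

## Covariance mining

`GMatrixMiner` searches for a network whose trait covariance matches a
target G-matrix.  *Network stress* is `ln(mean((C − G)²))` over all `T²`
elements, where `C` is the network's trait covariance estimated from
`indivs` simulated individuals with fresh N(0, 1) loci.  The natural log is
used; the worked two-trait example (mean squared deviation 2.1176×10⁻⁴,
stress ≈ −8.46) then sits well below the usual termination criterion of
−6.0, which a base-10 log would not.  The mean squared deviation is floored
at 10⁻³⁰⁰ before logging so a perfect match has finite stress.

Per iteration, the population of `npsize` networks (initialised i.i.d.
N(0, 1)):

1. **mutation** — each stored value independently, with probability
   `mutation_rate` (default 0.1), gains an additive N(0, `mutation_sd`²)
   perturbation.  `mutation_sd` defaults to 0.1: perturbations of order 1
   cannot settle a network onto targets requiring element errors of order
   0.05, while 0.1 converges on the two-trait benchmark in a handful of
   generations;
2. **crossover** — networks are shuffled and paired; each pair attempts
   crossover with probability `crossover_rate` (0.1), swapping each value
   with probability `swap_pr` (0.5).  The value multiset across a pair is
   conserved;
3. **evaluation** — every network's stress from a fresh loci sample
   (`indivs` = 1000 by default; evaluations are never frozen or reused);
4. **selection** — tournaments of `tournament_size` (4) drawn with
   replacement; the lowest-stress entrant wins, ties break to the first
   drawn.

The lowest-stress network ever seen is tracked and returned.  Because a
single sampling-based evaluation is noisy (with `indivs` = 1000 the noise
floor of the estimated stress is near −7), a candidate record is accepted —
and termination against `term_cri` declared — only after confirmation on a
fresh sample `confirm_factor` (10) times larger.  Without this, the
best-ever slot is captured by lucky draws (a winner's-curse bias) and the
returned network can be substantially worse than its recorded stress.
The result reports both the exact covariance `MᵀM` of the best network and
one final fresh sampling estimate; `stress_test` re-evaluates a network
repeatedly to gauge this sampling robustness.

## Genomes and inheritance

Asexually reproducing pests are haploid; sexually ("sexual" = monoecious,
"biparental" = dioecious) reproducing pests are diploid, with both founder
haplotypes carrying the mined network values and independent N(0, 1) loci.
Trait computation sums allele values at homologous loci; network values
are *averaged* across haplotypes, so haploid and diploid founders from the
same network share a trait scale.  (Summing network values instead would
square the composite map's scale through every layer.)  Note that diploid
founders' summed loci have variance 2 per locus, which doubles founder
trait variance relative to the mined target; this literal behaviour is the
default, and `founder_variance_preserving = True` instead scales founder
and immigrant loci by 1/√2 to keep the mined trait scale.

Gametes are formed by independent per-position swapping between the two
haplotypes with probability `crossover_pr` ∈ [0, 0.5] (complete
recombination at 0.5), modelling a single chromosome; a crossover *walk*
with toggling state would add linkage between neighbouring positions, which
the flattened genome order would make arbitrary, so independence was
chosen.  Mutation follows recombination: each value independently with
probability `mutation_pr` draws a standard normal that replaces
(`mutation_type = 0`) or adds to (`mutation_type = 1`) the old value.
Loci may always mutate; network values only within the first
`net_mu_layers` of the `1 + layers` blocks counted from the locus side
(`net_mu_dir = 1`) or the trait side (`net_mu_dir = 0`).  Each haplotype
mutates independently.  `net_mu_layers = 0` freezes the genetic
architecture, so trait covariances cannot evolve.

## Landscape

Farms are contiguous axis-aligned rectangles produced by a splitline
algorithm: the farm quota of a rectangle is split in two (⌈k/2⌉, ⌊k/2⌋) and
the rectangle is cut along its longer dimension at a line proportional to
the quota split, jittered ±4% and clamped so each side can hold its quota.
Areas stay within a factor ≈2 of each other.  A custom `terrain` matrix of
farm ids (1..farms, every id present, contiguity not required) can replace
the tessellation.

Crops and pesticides each have an independent rotation clock: an event
fires at the start of steps where `t mod period = 0` (`period` 0 disables
events).  Rotation modes: 1 — types unchanged; 2 — each farm draws
uniformly among the *other* types (read literally from "transition from one
type to another"; self-transitions are available through matrix mode); 3 —
type `t → (t mod n) + 1`; matrix — a per-farm Markov draw from the row of
the current type.  Every rotation event resets amounts on all cells to
`crop_per_cell` / `pesticide_per_cell` — including under mode 1, which is
how a single-crop landscape replenishes each season.  Between crop
rotations, crop amounts grow per step by a proportion or increment
(`crop_growth`, `crop_growth_type`); growth is skipped on the rotation step
itself, which starts from the reset amount.  There is no growth ceiling.

Coordinates are 0-based `(x, y)` with `x` the column.  Edge rules for
candidate positions: `torus` wraps modulo the dimensions; `sticky` clamps
to the boundary; `reflect` mirrors about the grid walls (period-`2d`
triangle fold, so arbitrary overshoots multi-bounce correctly); `leaky`
removes the pest.

## Pest ecology

Each time step runs: landscape change, aging (+1) and metabolism, feeding,
pesticide uptake, movement, reproduction, mortality, immigration, then one
statistics row.  Feeding, uptake, movement and reproduction each apply only
within inclusive age windows.  Because aging precedes everything else, a
pest born at step `t` first acts at age 1 in step `t+1`; age-0 activity
applies only to pests initialised at age 0 before their first step ages
them.

- **Feeding.**  Pests feed in a uniformly shuffled order, each taking
  `min(ability, crop remaining)` from its cell; the cell is depleted.  The
  vectorised implementation (per-cell cumulative consumption in shuffled
  order) is tested to match a literal sequential loop exactly.
- **Pesticide uptake** works identically but never depletes the cell.
  Uptake ability is clamped at zero, so a negative bound trait confers
  immunity (threshold trait).
- **Movement.**  Per bout (up to `movement_bouts`), in fresh random order,
  each pest draws a destination uniformly from the Chebyshev square of
  radius `move_distance` around it — the square includes its own cell —
  and the edge rule resolves the result.  If `feed_while_moving` /
  `pesticide_while_moving` are set and the pest is of feeding age, it
  feeds/uptakes on each arrival; a single per-step ability budget is
  shared across the main feed and all bouts (a bout never refreshes
  consumption capacity).
- **Reproduction.**  Asexual, monoecious, or female pests of reproductive
  age whose cumulative pesticide intake is within
  `pesticide_tolerated_repr` produce `Poisson(lambda_value)` offspring
  (`reproduction_type = "lambda"`) or `floor(total food /
  food_needed_repr)` (`"food_based"`).  Sexual modes require ≥1 potential
  mate (monoecious or male, reproductive age, within its own reproductive
  tolerance) within Chebyshev `mating_distance` — wrap-aware on a torus;
  the mother herself counts only if `selfing`.  Each offspring's sire is
  an independent uniform draw from the eligible mates (fair-raffle
  multiple mating).  Offspring appear on the mother's current cell at age
  0; in biparental mode sex is assigned 50:50.  If the step's cohort
  exceeds `K_on_birth` > 0, offspring are removed uniformly at random down
  to capacity.
- **Metabolism** subtracts `metabolism` from a pest's total food store
  (floored at zero, drawn proportionally across crop types) within its age
  window.
- **Mortality.**  A pest dies in a step if (i) its age exceeds `max_age`;
  (ii) once `age ≥ age_pesticide_threshold`, its summed pesticide intake
  exceeds `pesticide_tolerated_surv`; or (iii) exactly at
  `age = max_age_feed`, its total food is below `food_needed_surv` — a
  one-off checkpoint at the end of the feeding window, implementing "must
  eat X by the end of feeding age to survive".  Tolerances default to
  +infinity (no constraint).  Newborns pass through the same stage but are
  untouched by these rules unless their windows start at age 0.
- **Immigration.**  `Poisson(immigration_rate)` immigrants per step,
  initialised exactly like founders (random cell, `rand_age` rule, fresh
  N(0, 1) loci on the founding network) — resident evolution never affects
  immigrants.

Extinction is not an error; statistics continue and immigration can rescue
the population.

## Randomness and determinism

One `numpy` PCG64 generator drives everything, consumed in fixed program
order (mutation, crossover, evaluation, selection within mining; the
schedule order within the simulation).  Identical seed + configuration
gives bit-identical CSVs, which the suite asserts.

## Output

`population_data.csv` has one row per completed step: `time_step`,
`population_size`, `mean_age`, `sex_ratio` (females / (females + males);
blank for unsexed populations), mean cumulative food and pesticide consumed
per type, `mortality_rate` (deaths that step over the pre-mortality count),
and mean trait values.  `individuals.csv` (via `print_inds` / `print_last`)
adds per-pest state and flattened haplotypes; genomes reconstructed from it
reproduce the printed trait columns to 10⁻⁹.  Floats are written with 17
significant digits so `read_output_csv` round-trips them bit-exactly.
Column order is fixed by the package and stable.  `run_farm_sim` returns
the parameter record and the final landscape as a (5, xdim, ydim) array:
farm id, crop type, crop amount, pesticide type, pesticide amount.

## The bundled example and what tests show

`run_two_pesticide_example` mines a 3-locus, 2-layer network against
[[1, −0.4], [−0.4, 1]] (termination stress −6.0, ≤1000 generations) and
runs 160 steps on a 64×64 torus: nine splitline farms, one crop
(4 units/cell, reset every 16 steps), two pesticides (1 unit/cell, cycled
every 16 steps) whose uptake rates are traits 1 and 2 (means 0.1), food
ability 1/step, survival and reproduction food-based (1 unit each), any
pesticide intake lethal from age 2, lifespan 4 with feeding at 0–2,
movement (radius 2) at 3–4, reproduction at 4, random initial ages, and 10
expected immigrants per step.  Both mean uptake traits reliably evolve
negative within the run.

The simulated populations are a study system, not field data: loci are
abstract standard-normal quantitative alleles (no sequences, linkage maps,
dominance, or epistasis beyond the shared network), generations are
controlled by rigid age windows, and landscapes are rectangular grids.
Passing tests demonstrate the internal contracts above — conservation laws,
inheritance semantics, selection responding to the imposed mortality — not
calibration to any real pest.

Problem sizes in the test and acceptance runs (a few hundred networks, 10³
evaluation individuals, 64×64 landscapes, populations of order 10³–10⁴ for
160 steps, 3–10 seed replicates) were chosen so the full suite completes in
well under a minute while leaving the stochastic checks comfortable margins
(e.g. binomial/multinomial tolerances at ≥4σ).

## Known limitations

- Diploid founder trait variance is double the mined target by default
  (loci summing; `founder_variance_preserving` opts out).
- Pesticide survival/reproduction tolerances compare the *sum* of intake
  across pesticide types against a scalar; there is no per-type tolerance.
- Mate search is O(mothers × candidates) per step; sexual populations of
  ~10⁵ would need spatial indexing.
- No density dependence besides `K_on_birth`; no dispersal kernels beyond
  the uniform Chebyshev square; no raster/GIS terrain import (a plain
  integer matrix stands in).
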