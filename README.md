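# pestevol

Individual-based simulation of polygenic pesticide-resistance evolution in
agricultural pests on spatially explicit, rotating farm landscapes.

Managing pesticide resistance means understanding how selection acts on
*covarying* quantitative traits — an allele that confers resistance to one
pesticide may carry costs, or correlated susceptibilities, elsewhere.
`pestevol` is aimed at modellers of pest management and resistance evolution
who want resistance to emerge mechanistically from genetic architecture
rather than being imposed as a parameter.

The package has two halves:

1. **Covariance mining.** Each pest genome contains a layered linear
   genotype→phenotype network: a row vector of `L` locus values is
   multiplied through an `L×T` matrix and then `layers` successive `T×T`
   matrices to give `T` trait values.  With loci drawn i.i.d. N(0, 1), a
   network with composite map `M` produces traits with covariance `MᵀM`.
   An evolutionary algorithm (`GMatrixMiner`) — mutation, crossover between
   networks, and tournament selection on *network stress*, the natural log
   of the mean squared deviation between a network's estimated trait
   covariance and a target **G**-matrix — searches for a network whose
   traits realise a user-specified covariance structure.

2. **Farm simulation.** A pest population carrying a mined network in every
   genome (haploid or diploid) lives on an `xdim×ydim` grid tiled into
   farms.  Each farm holds one crop and one pesticide at a time; both
   rotate independently on fixed clocks (no rotation, random switch,
   numeric cycling, or an arbitrary Markov transition matrix).  Each time
   step runs landscape change, aging and metabolism, feeding (depleting),
   pesticide uptake (non-depleting), movement bouts, reproduction,
   mortality, and Poisson immigration, all gated by inclusive age windows.
   Any of ten life-history parameters (`move_distance`, `food_consume`,
   `pesticide_consume`, …) can be bound to an evolving trait by passing
   `"Tj"` instead of a number; bound uptake rates are threshold traits
   (negative values mean no uptake, hence immunity).

## Worked example

Mine a network for two traits with variances 1 and covariance −0.4 (a
susceptibility trade-off), then simulate 160 time steps (ten 16-step
growing seasons) on a 64×64 torus with nine farms and two rotating
pesticides whose uptake rates are the two traits:

```python
from pestevol import run_two_pesticide_example

mined, result = run_two_pesticide_example(seed=1, output_dir=".")
print(mined.summary())
print(result.summary())
```

```
Covariance mining result
========================================
loci: 3   layers: 2   traits: 2
generations run: 5   converged: True
final stress (fresh sample): -5.9662
expected stress (noise-free): -6.1937
target covariance:
[[ 1.  -0.4]
 [-0.4  1. ]]
achieved (expected) covariance:
[[ 0.933646  -0.4433748]
 [-0.4433748  0.9982553]]

Farm simulation result
========================================
time steps: 160
final population size: 1893
final mean traits: trait_1=-0.5507, trait_2=-0.5618
final mortality rate: 0.3436
```

The mined network's traits covary at −0.44 against the −0.4 target (the
termination stress of −6 corresponds to a root-mean-square element error of
about 0.05).  In the simulation, any pesticide uptake before age 2 is
lethal, so both mean uptake traits are driven negative within a few
seasons — the population evolves resistance to both pesticides, and the
trade-off encoded in the negative trait covariance is too weak to preserve
susceptibility to either.  `population_data.csv` holds the per-step time
series (population size, mean age, sex ratio, mean food and pesticide
consumed per type, mortality rate, mean traits); `individuals.csv` holds
every pest's state and flattened genome for the final step.

The same pipeline is scriptable from the shell:

```sh
pestevol mine --gmatrix '1,-0.4;-0.4,1' --loci 3 --layers 2 --seed 1 --out net.txt
pestevol simulate --config sim.yml --network net.txt --seed 1 --out-dir out/
pestevol example --seed 1 --out-dir out/
```

## Library surface

- `GMatrixMiner(gmatrix, loci, layers, ...).fit(seed)` → `MiningResult`
  (best network, achieved covariance, stress trajectory, `summary()`);
  `mine_gmatrix`, `stress_test` are functional equivalents.
- `FarmSimulation(SimConfig(...), mined).run(seed)` → `SimulationResult`
  (parameter record, final landscape array, population time series,
  `summary()`); `run_farm_sim` returns the two-element
  (parameters, landscape-array) contract directly.
- `pestevol.network`, `.genome`, `.landscape`, `.ecology` expose the
  building blocks (trait computation, inheritance, splitline farm
  tessellation, edge rules, the per-step functions) for custom experiments.

No plotting functions are included; the CSV outputs are designed to be
plotted with pandas/matplotlib directly.

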