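"""Running simulations and writing their output.

:class:`FarmSimulation` assembles a validated configuration, a mined
genotype->phenotype network, and a landscape into a runnable simulation;
``run()`` executes the time steps and returns a :class:`SimulationResult`
holding the population time series, the final landscape array, and the full
parameter record.  Population statistics always go to
``population_data.csv`` in the output directory; individual-level rows
(including flattened genomes) go to ``individuals.csv`` when requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import SimConfig
from .ecology import (
    SEX_NAMES,
    SimState,
    init_population,
    run_time_step,
)
from .genome import GenomeLayout
from .landscape import (
    Landscape,
    RotationPolicy,
    init_assignments,
    load_terrain,
    splitline_farms,
)
from .mining import GMatrixMiner, MiningResult
from .network import Network

__all__ = [
    "FarmSimulation",
    "SimulationResult",
    "run_farm_sim",
    "parse_config",
    "run_two_pesticide_example",
    "read_output_csv",
    "POPULATION_FILE",
    "INDIVIDUALS_FILE",
]

POPULATION_FILE = "population_data.csv"
INDIVIDUALS_FILE = "individuals.csv"


def read_output_csv(path) -> pd.DataFrame:
    """Read a simulation CSV so floats round-trip bit-exactly.

    Output files are written with enough digits to be lossless; pandas'
    fast float parser can drop the last ulp, so reading goes through the
    round-trip parser.
    """
    return pd.read_csv(path, float_precision="round_trip")


@dataclass
class SimulationResult:
    """Everything a finished run produced."""

    params: dict
    final_landscape: np.ndarray          # (5, xdim, ydim) layered array
    population_data: pd.DataFrame
    individuals: pd.DataFrame | None
    population_path: Path | None
    individuals_path: Path | None

    def summary(self) -> str:
        df = self.population_data
        lines = [
            "Farm simulation result",
            "=" * 40,
            f"time steps: {len(df)}",
        ]
        if len(df):
            last = df.iloc[-1]
            lines.append(f"final population size: {int(last['population_size'])}")
            trait_cols = [c for c in df.columns if c.startswith("mean_trait_")]
            vals = ", ".join(f"{c[len('mean_'):]}={last[c]:+.4f}" for c in trait_cols)
            lines.append(f"final mean traits: {vals}")
            lines.append(f"final mortality rate: {last['mortality_rate']:.4f}")
        if self.population_path is not None:
            lines.append(f"population data: {self.population_path}")
        if self.individuals_path is not None:
            lines.append(f"individual data: {self.individuals_path}")
        return "\n".join(lines)


def _stats_columns(cfg: SimConfig, n_traits: int) -> list[str]:
    cols = ["time_step", "population_size", "mean_age", "sex_ratio"]
    cols += [f"mean_food_consumed_{j + 1}" for j in range(cfg.crop_number)]
    cols += [f"mean_pesticide_consumed_{j + 1}" for j in range(cfg.pesticide_number)]
    cols += ["mortality_rate"]
    cols += [f"mean_trait_{j + 1}" for j in range(n_traits)]
    return cols


def _individual_frame(state: SimState) -> pd.DataFrame:
    pop, cfg = state.pop, state.cfg
    data: dict = {
        "time_step": np.full(pop.size, state.t),
        "id": pop.ids,
        "age": pop.age,
        "sex": [SEX_NAMES[int(s)] for s in pop.sex],
        "x": pop.x,
        "y": pop.y,
    }
    for j in range(cfg.crop_number):
        data[f"food_consumed_{j + 1}"] = pop.food[:, j]
    for j in range(cfg.pesticide_number):
        data[f"pesticide_consumed_{j + 1}"] = pop.pesticide[:, j]
    for j in range(state.network.traits):
        data[f"trait_{j + 1}"] = pop.traits[:, j]
    G = pop.layout.length
    for h in range(pop.ploidy):
        for g in range(G):
            data[f"hap{h + 1}_{g + 1}"] = pop.haps[:, h, g]
    return pd.DataFrame(data)


class FarmSimulation:
    """A configured, runnable pest simulation.

    Parameters
    ----------
    config : SimConfig
        Validated run parameters.
    mined : MiningResult or Network
        The mined genotype->phenotype network founding every genome.
    """

    def __init__(self, config: SimConfig, mined: MiningResult | Network):
        self.config = config
        self.network = mined.best_network if isinstance(mined, MiningResult) else mined
        config.check_traits(self.network.traits)

    def _build_state(self, rng: np.random.Generator) -> SimState:
        cfg = self.config
        if cfg.terrain is not None:
            farm_grid = load_terrain(cfg.terrain, cfg.farms)
        else:
            farm_grid = splitline_farms(cfg.xdim, cfg.ydim, cfg.farms, rng)
        crop_assign = init_assignments(cfg.farms, cfg.crop_number, cfg.crop_init, rng)
        pest_assign = init_assignments(
            cfg.farms, cfg.pesticide_number, cfg.pesticide_init, rng
        )
        landscape = Landscape.build(
            farm_grid, crop_assign, pest_assign,
            cfg.crop_per_cell, cfg.pesticide_per_cell, cfg.land_edge,
        )
        pop = init_population(cfg, self.network, landscape, rng)
        state = SimState(
            cfg=cfg,
            network=self.network,
            landscape=landscape,
            pop=pop,
            rng=rng,
            crop_policy=RotationPolicy(
                cfg.crop_rotation_type, cfg.crop_rotation_time,
                cfg.crop_per_cell, cfg.crop_number,
            ),
            pesticide_policy=RotationPolicy(
                cfg.pesticide_rotation_type, cfg.pesticide_rotation_time,
                cfg.pesticide_per_cell, cfg.pesticide_number,
            ),
            crop_assign=crop_assign,
            pesticide_assign=pest_assign,
            next_id=pop.size,
        )
        return state

    def run(
        self,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
        output_dir: str | Path | None = None,
        write: bool = True,
    ) -> SimulationResult:
        """Execute the simulation and (by default) write the CSV output."""
        cfg = self.config
        if rng is None:
            rng = np.random.default_rng(seed)
        out_dir = Path(cfg.output_dir if output_dir is None else output_dir)
        pop_path = ind_path = None
        if write:
            if not out_dir.is_dir():
                raise IOError(f"output directory {out_dir} does not exist")
            pop_path = out_dir / POPULATION_FILE
            if cfg.print_inds or cfg.print_last:
                ind_path = out_dir / INDIVIDUALS_FILE
            if cfg.print_inds and cfg.time_steps > 10:
                warnings.warn(
                    "print_inds=True writes every individual every step and can "
                    "create extremely large files; consider print_last=True",
                    stacklevel=2,
                )

        state = self._build_state(rng)
        ind_frames: list[pd.DataFrame] = []
        for _ in range(cfg.time_steps):
            run_time_step(state)
            if cfg.print_gens:
                print(f"time step {state.t}: N = {state.pop.size}")
            if cfg.print_inds:
                ind_frames.append(_individual_frame(state))
        if cfg.print_last and not cfg.print_inds:
            ind_frames.append(_individual_frame(state))

        cols = _stats_columns(cfg, self.network.traits)
        pop_df = pd.DataFrame(state.stats_rows, columns=cols)
        ind_df = pd.concat(ind_frames, ignore_index=True) if ind_frames else None
        if write:
            # %.17g keeps float round-trips through the CSV bit-exact
            pop_df.to_csv(pop_path, index=False, float_format="%.17g")
            if ind_path is not None and ind_df is not None:
                ind_df.to_csv(ind_path, index=False, float_format="%.17g")

        params = self.config.to_param_record()
        return SimulationResult(
            params=params,
            final_landscape=state.landscape.as_array(),
            population_data=pop_df,
            individuals=ind_df,
            population_path=pop_path,
            individuals_path=ind_path,
        )


def run_farm_sim(
    cfg: SimConfig,
    mined: MiningResult | Network,
    seed: int | None = None,
    output_dir: str | Path | None = None,
) -> tuple[dict, np.ndarray]:
    """Run a simulation; returns (parameter record, final landscape array).

    The population statistics CSV is always written; individual-level data
    follows the ``print_inds`` / ``print_last`` flags.
    """
    sim = FarmSimulation(cfg, mined)
    res = sim.run(seed=seed, output_dir=output_dir)
    return res.params, res.final_landscape


def parse_config(source) -> SimConfig:
    """Build a validated :class:`SimConfig` from a dict or a YAML file path."""
    if isinstance(source, SimConfig):
        return source
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    elif isinstance(source, dict):
        data = dict(source)
    else:
        raise TypeError("parse_config takes a SimConfig, dict, or YAML path")
    valid = {f for f in SimConfig.__dataclass_fields__ if f != "bindings"}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    if "terrain" in data and data["terrain"] is not None:
        data["terrain"] = np.asarray(data["terrain"], dtype=int)
    return SimConfig(**data)


def two_pesticide_config(**overrides) -> SimConfig:
    """The bundled worked example: one crop, two rotating pesticides whose
    uptake rates are the two covarying traits (a susceptibility trade-off).

    64 x 64 torus landscape, nine farms, 16-step growing seasons, asexual
    pests with a 5-step life cycle and 10 expected immigrants per step.
    """
    base = dict(
        repro="asexual",
        pesticide_number=2,
        pesticide_init="random",
        pesticide_consume=("T1", "T2"),
        farms=9,
        pesticide_rotation_time=16,
        pesticide_rotation_type=3,
        pesticide_tolerated_surv=0.0,
        pesticide_per_cell=1.0,
        crop_rotation_time=16,
        crop_number=1,
        crop_per_cell=4.0,
        food_consume=1.0,
        reproduction_type="food_based",
        food_needed_surv=1.0,
        food_needed_repr=1.0,
        max_age=4,
        min_age_feed=0,
        max_age_feed=2,
        min_age_move=3,
        max_age_move=4,
        min_age_reproduce=4,
        max_age_reproduce=4,
        age_pesticide_threshold=2,
        rand_age=True,
        move_distance=2,
        immigration_rate=10.0,
        time_steps=160,
        print_last=True,
        xdim=64,
        ydim=64,
        trait_means=(0.1, 0.1),
        land_edge="torus",
    )
    base.update(overrides)
    return SimConfig(**base)


def run_two_pesticide_example(
    seed: int = 0,
    output_dir: str | Path | None = ".",
    mined: MiningResult | None = None,
    **config_overrides,
) -> tuple[MiningResult, SimulationResult]:
    """Mine a 3-locus / 2-layer network targeting covariance -0.4 between the
    two pesticide-uptake traits, then run the two-pesticide rotation example.

    Returns the mining result and the simulation result.
    """
    rng = np.random.default_rng(seed)
    if mined is None:
        miner = GMatrixMiner(
            [[1.0, -0.4], [-0.4, 1.0]], loci=3, layers=2,
            term_cri=-6.0, max_gen=1000,
        )
        mined = miner.fit(rng=rng)
    cfg = two_pesticide_config(**config_overrides)
    sim = FarmSimulation(cfg, mined)
    result = sim.run(rng=rng, output_dir=output_dir, write=output_dir is not None)
    return mined, result
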