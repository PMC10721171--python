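"""Simulation configuration: every run parameter, validated, with optional
trait bindings.

Any of ten ecology parameters may be bound to an evolving trait by passing
the string ``"Tj"`` (1-based trait number ``j``) in place of a number, e.g.
``move_distance="T1"`` or ``pesticide_consume=("T1", "T2")``.  At most 10
bindings are allowed per simulation.  Bound parameters that must be
non-negative are clamped at zero per pest (threshold traits), and bound
integer parameters are floored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields

import numpy as np

from .landscape import EDGE_MODES, MAX_TYPES

__all__ = ["SimConfig", "BINDABLE_PARAMETERS", "parse_trait_token"]

#: Parameters that accept a "Tj" trait binding.  Vector-valued parameters
#: (food_consume, pesticide_consume) may bind each element separately.
BINDABLE_PARAMETERS = (
    "move_distance",
    "food_needed_surv",
    "pesticide_tolerated_surv",
    "food_needed_repr",
    "pesticide_tolerated_repr",
    "mating_distance",
    "lambda_value",
    "movement_bouts",
    "metabolism",
    "food_consume",
    "pesticide_consume",
)

MAX_BINDINGS = 10

#: Bound parameters clamped at zero (threshold traits) and, where integer,
#: floored, when realised from a pest's trait value.
NONNEG_REAL_PARAMS = {"food_consume", "pesticide_consume", "metabolism", "lambda_value"}
NONNEG_INT_PARAMS = {"move_distance", "mating_distance", "movement_bouts"}

_TRAIT_RE = re.compile(r"^[Tt](\d+)$")


def parse_trait_token(value):
    """Return the 1-based trait index for a "Tj" string, else None."""
    if isinstance(value, str):
        m = _TRAIT_RE.match(value.strip())
        if not m:
            raise ValueError(f"cannot parse trait binding {value!r}; expected 'Tj'")
        return int(m.group(1))
    return None


def _parse_bindable_scalar(value):
    """-> (numeric value or None, trait index or None)."""
    idx = parse_trait_token(value) if isinstance(value, str) else None
    if idx is not None:
        return None, idx
    return float(value), None


def _parse_bindable_vector(value, n: int, name: str):
    """-> (numeric array, list of trait indices or None, one per element)."""
    if isinstance(value, (int, float, str)):
        value = [value] * n
    value = list(value)
    if len(value) != n:
        raise ValueError(f"{name} must have {n} element(s), got {len(value)}")
    nums = np.zeros(n)
    idxs: list[int | None] = []
    for i, v in enumerate(value):
        num, idx = _parse_bindable_scalar(v)
        idxs.append(idx)
        nums[i] = 0.0 if num is None else num
    return nums, idxs


@dataclass
class SimConfig:
    """All run parameters for the farm simulation.

    Ages are in time steps and windows are inclusive; ``None`` for a
    ``max_age_*`` field means "up to max_age".  Rotation times of 0 disable
    rotation events entirely.
    """

    # reproduction system
    repro: str = "asexual"              # "asexual" | "sexual" | "biparental"
    selfing: bool = False
    reproduction_type: str = "lambda"   # "lambda" | "food_based"
    lambda_value: float | str = 1.0
    food_needed_repr: float | str = 1.0
    pesticide_tolerated_repr: float | str | None = None
    mating_distance: int | str = 0
    K_on_birth: int = 0                 # 0 disables the birth carrying capacity

    # time & landscape
    time_steps: int = 100
    xdim: int = 10
    ydim: int = 10
    farms: int = 1
    terrain: np.ndarray | None = None
    land_edge: str = "torus"

    # crops
    crop_number: int = 1
    crop_init: object = "random"
    crop_rotation_time: int = 0
    crop_rotation_type: object = 1
    crop_per_cell: float = 1.0
    crop_growth: float = 0.0
    crop_growth_type: str = "increment"

    # pesticides
    pesticide_number: int = 1
    pesticide_init: object = "random"
    pesticide_rotation_time: int = 0
    pesticide_rotation_type: object = 1
    pesticide_per_cell: float = 0.0

    # feeding & survival
    food_consume: object = 1.0
    pesticide_consume: object = 0.0
    food_needed_surv: float | str = 0.0
    pesticide_tolerated_surv: float | str | None = None
    metabolism: float | str = 0.0

    # movement
    movement_bouts: int | str = 1
    move_distance: int | str = 1
    feed_while_moving: bool = False
    pesticide_while_moving: bool = False

    # age structure
    max_age: int = 9
    min_age_feed: int = 0
    max_age_feed: int | None = None
    min_age_move: int = 0
    max_age_move: int | None = None
    min_age_reproduce: int = 0
    max_age_reproduce: int | None = None
    min_age_metabolism: int = 0
    max_age_metabolism: int | None = None
    age_pesticide_threshold: int = 0
    rand_age: bool = False

    # population & evolution
    N0: int = 1000
    #: scale diploid founder/immigrant loci by 1/sqrt(2) so summed allele
    #: values keep the mined network's trait variance (off: literal summing,
    #: which doubles founder trait variance)
    founder_variance_preserving: bool = False
    immigration_rate: float = 0.0
    crossover_pr: float = 0.0
    mutation_pr: float = 0.0
    mutation_type: int = 0
    net_mu_layers: int = 0
    net_mu_dir: int = 1
    trait_means: object = None

    # output
    print_inds: bool = False
    print_last: bool = False
    print_gens: bool = False
    output_dir: str = "."

    # derived (filled by validation)
    bindings: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.repro not in ("asexual", "sexual", "biparental"):
            raise ValueError("repro must be 'asexual', 'sexual', or 'biparental'")
        if self.reproduction_type not in ("lambda", "food_based"):
            raise ValueError("reproduction_type must be 'lambda' or 'food_based'")
        if self.land_edge not in EDGE_MODES:
            raise ValueError(f"land_edge must be one of {EDGE_MODES}")
        if self.time_steps < 0:
            raise ValueError("time_steps must be >= 0")
        if self.terrain is None and (self.xdim < 1 or self.ydim < 1):
            raise ValueError("xdim and ydim must be >= 1")
        if self.farms < 1:
            raise ValueError("farms must be >= 1")
        for name in ("crop_number", "pesticide_number"):
            v = getattr(self, name)
            if not 1 <= v <= MAX_TYPES:
                raise ValueError(f"{name} must be in 1..{MAX_TYPES}")
        if self.max_age < 0:
            raise ValueError("max_age must be >= 0")
        for name in ("crop_per_cell", "pesticide_per_cell", "crop_growth",
                     "immigration_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.N0 < 0 or self.K_on_birth < 0:
            raise ValueError("N0 and K_on_birth must be >= 0")
        if not 0.0 <= self.crossover_pr <= 0.5:
            raise ValueError("crossover_pr must be in [0, 0.5]")
        if not 0.0 <= self.mutation_pr <= 1.0:
            raise ValueError("mutation_pr must be in [0, 1]")
        if self.mutation_type not in (0, 1):
            raise ValueError("mutation_type must be 0 or 1")
        if self.net_mu_dir not in (0, 1):
            raise ValueError("net_mu_dir must be 0 or 1")
        for name in ("min_age_feed", "min_age_move", "min_age_reproduce",
                     "min_age_metabolism", "age_pesticide_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= self.max_age:
                raise ValueError(f"{name} must be in [0, max_age]")
        for name in ("max_age_feed", "max_age_move", "max_age_reproduce",
                     "max_age_metabolism"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= self.max_age:
                raise ValueError(f"{name} must be None or in [0, max_age]")
        self._parse_bindings()

    def _parse_bindings(self) -> None:
        """Parse "Tj" tokens on bindable parameters into self.bindings."""
        b: dict = {}
        n_bound = 0
        for name in BINDABLE_PARAMETERS:
            raw = getattr(self, name)
            if name == "food_consume":
                nums, idxs = _parse_bindable_vector(raw, self.crop_number, name)
                b[name] = (nums, idxs)
                n_bound += sum(i is not None for i in idxs)
            elif name == "pesticide_consume":
                nums, idxs = _parse_bindable_vector(raw, self.pesticide_number, name)
                b[name] = (nums, idxs)
                n_bound += sum(i is not None for i in idxs)
            else:
                if raw is None:  # tolerances default to "no limit"
                    b[name] = (np.inf, None)
                    continue
                num, idx = _parse_bindable_scalar(raw)
                b[name] = (num, idx)
                n_bound += idx is not None
        if n_bound > MAX_BINDINGS:
            raise ValueError(
                f"at most {MAX_BINDINGS} parameters may be bound to traits, "
                f"got {n_bound}"
            )
        self.bindings = b

    def check_traits(self, n_traits: int) -> None:
        """Verify every bound trait index exists for a T-trait network."""
        for name, val in self.bindings.items():
            idxs = val[1]
            idx_list = idxs if isinstance(idxs, list) else [idxs]
            for i in idx_list:
                if i is not None and not 1 <= i <= n_traits:
                    raise ValueError(
                        f"{name} is bound to trait {i} but the network has only "
                        f"{n_traits} traits"
                    )
        if self.trait_means is not None:
            tm = np.asarray(self.trait_means, dtype=float)
            if tm.shape != (n_traits,):
                raise ValueError(
                    f"trait_means must have length {n_traits}, got {tm.shape}"
                )

    # -- resolved accessors ----------------------------------------------
    def age_window(self, what: str) -> tuple[int, int]:
        lo = getattr(self, f"min_age_{what}")
        hi = getattr(self, f"max_age_{what}")
        return lo, self.max_age if hi is None else hi

    def resolved_trait_means(self, n_traits: int) -> np.ndarray:
        if self.trait_means is None:
            return np.zeros(n_traits)
        return np.asarray(self.trait_means, dtype=float)

    def param_values(self, name: str, traits: np.ndarray) -> np.ndarray:
        """Per-pest realised value of a bindable scalar parameter.

        ``traits`` has shape (N, T).  Non-negative parameters are clamped at
        zero and integer ones floored when trait-bound.
        """
        num, idx = self.bindings[name]
        n = traits.shape[0]
        if idx is None:
            return np.full(n, num)
        vals = traits[:, idx - 1].copy()
        if name in NONNEG_REAL_PARAMS or name in NONNEG_INT_PARAMS:
            vals = np.maximum(vals, 0.0)
        if name in NONNEG_INT_PARAMS:
            vals = np.floor(vals)
        return vals

    def consume_abilities(self, name: str, traits: np.ndarray) -> np.ndarray:
        """Per-pest, per-type consumption ability matrix (N, n_types).

        Negative abilities (from negative bound traits) clamp to zero:
        consumption is a threshold trait.
        """
        nums, idxs = self.bindings[name]
        n = traits.shape[0]
        out = np.tile(nums, (n, 1))
        for j, idx in enumerate(idxs):
            if idx is not None:
                out[:, j] = traits[:, idx - 1]
        return np.maximum(out, 0.0)

    def to_param_record(self) -> dict:
        """Flat record of every configured parameter value."""
        rec = {}
        for f in fields(self):
            if f.name in ("bindings", "terrain"):
                continue
            v = getattr(self, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            rec[f.name] = v
        rec["terrain"] = None if self.terrain is None else np.asarray(self.terrain).tolist()
        return rec
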