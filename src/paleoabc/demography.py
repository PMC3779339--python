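"""Demographic scenarios, priors and unit conversions.

Four stock scenarios mirror the classic refugial-isolation analysis of
Holarctic woolly-mammoth mtDNA:

* ``1A`` — three populations (the three mtDNA clades: ``europe``,
  ``siberia``, ``america``) that split simultaneously from a common
  ancestral population at ``T_split``, all with constant size.
* ``1B`` — as 1A, but each population passed through a simultaneous
  bottleneck followed by exponential growth starting (forward in time) at
  ``T_growth``; ``T_growth < T_split`` is enforced by rejection at the
  prior-sampling stage.
* ``2A`` — two populations (``eurasia``, ``north_america``) that diverged at
  ``T_split`` with no subsequent gene flow.
* ``2B`` — as 2A, with forward-time gene flow from Eurasia into North
  America after the divergence (backwards in time: lineages currently in
  North America jump to Eurasia at rate ``mig_rate`` per generation).

All user-facing times are calendar years BP; sizes are female effective
population sizes (haploid-equivalent, mtDNA).  Inside the simulator time is
continuous, in generations, measured backwards from 0 = the most recent
sample epoch, so a realized scenario is produced with a time offset equal to
the youngest sample age.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .mutation import MutationModel

DEFAULT_GENERATION_TIME = 15.0  # years; sensitivity analyses use 20

MODEL1_DEMES = ("europe", "siberia", "america")
MODEL2_DEMES = ("eurasia", "north_america")
ANCESTRAL = "ancestral"


def years_to_generations(age: float, generation_time: float = DEFAULT_GENERATION_TIME) -> float:
    """Convert an age in calendar years to coalescent generations."""
    if generation_time <= 0:
        raise ValueError("generation_time must be > 0")
    if age < 0:
        raise ValueError("age must be >= 0")
    return age / generation_time


def per_generation_rate(
    rate_per_site_per_myr: float, generation_time: float = DEFAULT_GENERATION_TIME
) -> float:
    """Convert a substitution rate per site per Myr into a per-generation rate.

    A rate quoted as "9.56% per site per 10^6 years" is 0.0956
    substitutions/site/Myr and maps to 0.0956e-6 * generation_time per site
    per generation.
    """
    if rate_per_site_per_myr < 0 or generation_time <= 0:
        raise ValueError("rates and generation time must be positive")
    return rate_per_site_per_myr * 1e-6 * generation_time


@dataclass(frozen=True)
class UniformPrior:
    """Uniform prior on [lower, upper] in the parameter's natural units."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"require lower < upper, got [{self.lower}, {self.upper}]")

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.lower, self.upper))


@dataclass
class DemeConfig:
    """A deme's present-day size and optional growth phase.

    ``growth_start`` is the backward time (generations BP) at which
    exponential growth began forward in time; before it the deme sat at
    ``pre_growth_size``.
    """

    id: str
    N0: float
    growth_start: float | None = None
    pre_growth_size: float | None = None

    def __post_init__(self) -> None:
        if self.N0 < 1:
            raise ValueError(f"deme {self.id}: N0 must be >= 1")
        if self.growth_start is not None and (
            self.pre_growth_size is None or self.pre_growth_size < 1
        ):
            raise ValueError(f"deme {self.id}: growth requires pre_growth_size >= 1")


@dataclass(frozen=True)
class DemographicEvent:
    """A scheduled backward-time event: merge of demes or a resize."""

    time: float  # generations BP
    kind: str  # "merge" | "resize"
    params: Mapping[str, object]

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("event time must be > 0")
        if self.kind not in ("merge", "resize"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class MigrationSpec:
    """Backward-time lineage-movement probabilities per generation.

    ``rates[i, j]`` is the per-generation probability that a lineage
    currently in deme ``demes[i]`` moves (backwards in time) to
    ``demes[j]``; active on [0, ``active_until``) generations BP.
    """

    demes: tuple[str, ...]
    rates: np.ndarray
    active_until: float = math.inf

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (len(self.demes), len(self.demes)):
            raise ValueError("migration matrix shape must match deme count")
        if (self.rates < 0).any() or (self.rates > 1).any():
            raise ValueError("migration rates must lie in [0, 1]")
        if (self.rates.sum(axis=1) > 1 + 1e-12).any():
            raise ValueError("migration row sums must be <= 1")


# ---------------------------------------------------------------------------
# Realized (concrete) demography consumed by the simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Epoch:
    """Piecewise-exponential size trajectory segment (backward time).

    Within the epoch ``N(t) = size * exp(rate * (t - start))`` for
    ``t >= start``; ``rate < 0`` means the deme shrinks backwards in time
    (i.e. grew forward in time).
    """

    start: float
    size: float
    rate: float = 0.0


@dataclass
class Demography:
    """Fully realized multi-deme history: epochs, merges, migration."""

    demes: dict[str, list[Epoch]]
    merges: list[tuple[float, tuple[str, ...], str]] = field(default_factory=list)
    migration: MigrationSpec | None = None

    def __post_init__(self) -> None:
        for d, epochs in self.demes.items():
            if not epochs:
                raise ValueError(f"deme {d}: needs at least one epoch")
            for e in epochs:
                if e.size <= 0:
                    raise ValueError(f"deme {d}: zero or negative size")
            starts = [e.start for e in epochs]
            if starts != sorted(starts) or starts[0] != 0.0:
                raise ValueError(f"deme {d}: epochs must start at 0 and be sorted")
        for t, sources, dest in self.merges:
            if dest not in self.demes:
                raise ValueError(f"merge destination {dest!r} unknown")
            for s in sources:
                if s not in self.demes:
                    raise ValueError(f"merge source {s!r} unknown")
        self.merges = sorted(self.merges, key=lambda m: m[0])


# ---------------------------------------------------------------------------
# Scenario specification (parameters bound to priors or fixed values)
# ---------------------------------------------------------------------------

_MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "1A": ("N_ef", "N_anc", "T_split"),
    "1B": ("N_ef", "N_anc", "T_split", "T_growth", "bottleneck_frac"),
    "2A": ("N_eurasia", "N_america", "N_anc", "T_split"),
    "2B": ("N_eurasia", "N_america", "N_anc", "T_split", "mig_rate"),
}

_SIZE_PRIOR = UniformPrior(100.0, 60_000.0)

DEFAULT_PRIORS: dict[str, dict[str, UniformPrior]] = {
    "1A": {
        "N_ef": _SIZE_PRIOR,
        "N_anc": _SIZE_PRIOR,
        "T_split": UniformPrior(120_000.0, 400_000.0),
    },
    "1B": {
        "N_ef": _SIZE_PRIOR,
        "N_anc": _SIZE_PRIOR,
        "T_split": UniformPrior(120_000.0, 400_000.0),
        "T_growth": UniformPrior(60_000.0, 160_000.0),
        "bottleneck_frac": UniformPrior(0.01, 1.0),
    },
    "2A": {
        "N_eurasia": _SIZE_PRIOR,
        "N_america": _SIZE_PRIOR,
        "N_anc": _SIZE_PRIOR,
        "T_split": UniformPrior(20_000.0, 140_000.0),
    },
    "2B": {
        "N_eurasia": _SIZE_PRIOR,
        "N_america": _SIZE_PRIOR,
        "N_anc": _SIZE_PRIOR,
        "T_split": UniformPrior(20_000.0, 140_000.0),
        "mig_rate": UniformPrior(0.0, 0.01),
    },
}

_MAX_REJECTION_TRIES = 10_000


class ScenarioSpec:
    """A demographic model with named parameters bound to priors or values.

    Parameters are in natural units: sizes in individuals (female effective),
    times in calendar years BP, migration in per-generation probability.
    """

    def __init__(
        self,
        model_id: str,
        params: Mapping[str, UniformPrior | float],
        generation_time: float = DEFAULT_GENERATION_TIME,
        mutation: MutationModel | None = None,
        builder: Callable[[Mapping[str, float], float], Demography] | None = None,
    ):
        if model_id not in _MODEL_PARAMS and model_id != "custom":
            raise ValueError(f"unknown model_id {model_id!r}")
        if model_id == "custom" and builder is None:
            raise ValueError("custom scenarios require a builder callable")
        if generation_time <= 0:
            raise ValueError("generation_time must be > 0")
        if model_id != "custom":
            required = set(_MODEL_PARAMS[model_id])
            got = set(params)
            if required != got:
                raise ValueError(
                    f"model {model_id} requires parameters {sorted(required)}, got {sorted(got)}"
                )
        self.model_id = model_id
        self.params: dict[str, UniformPrior | float] = dict(params)
        self.generation_time = float(generation_time)
        self.mutation = mutation if mutation is not None else MutationModel()
        self._builder = builder

    # -- priors ------------------------------------------------------------
    @property
    def deme_ids(self) -> tuple[str, ...]:
        if self.model_id in ("1A", "1B"):
            return MODEL1_DEMES
        if self.model_id in ("2A", "2B"):
            return MODEL2_DEMES
        return ()

    @property
    def free_params(self) -> list[str]:
        return [k for k, v in self.params.items() if isinstance(v, UniformPrior)]

    def _valid(self, draw: Mapping[str, float]) -> bool:
        if self.model_id == "1B":
            return draw["T_growth"] < draw["T_split"]
        return True

    def sample_params(self, rng: np.random.Generator | int) -> dict[str, float]:
        """Draw all free parameters from their priors.

        Draws violating structural constraints (model 1B requires
        ``T_growth < T_split``) are rejected and redrawn.
        """
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        for _ in range(_MAX_REJECTION_TRIES):
            draw = {
                k: (v.sample(rng) if isinstance(v, UniformPrior) else float(v))
                for k, v in self.params.items()
            }
            if self._valid(draw):
                return draw
        raise RuntimeError("could not draw structurally valid parameters from the priors")

    # -- realization -------------------------------------------------------
    def realize(
        self, draw: Mapping[str, float], time_offset_years: float = 0.0
    ) -> Demography:
        """Build the concrete multi-deme history for one parameter draw.

        ``time_offset_years`` anchors backward time 0 at the youngest sample:
        an event at ``T`` years BP sits at ``(T - offset) / generation_time``
        generations.
        """
        if not self._valid(draw):
            raise ValueError("parameter draw violates structural constraints")
        g = self.generation_time

        def gens(t_years: float) -> float:
            t = (t_years - time_offset_years) / g
            if t <= 0:
                raise ValueError(
                    f"event time {t_years} yr BP does not postdate the youngest sample"
                )
            return t

        if self.model_id == "custom":
            return self._builder(draw, time_offset_years)

        if self.model_id in ("1A", "1B"):
            t1 = gens(draw["T_split"])
            demes: dict[str, list[Epoch]] = {}
            if self.model_id == "1A":
                for d in MODEL1_DEMES:
                    demes[d] = [Epoch(0.0, draw["N_ef"])]
            else:
                t0 = gens(draw["T_growth"])
                n_ef = draw["N_ef"]
                n_b = max(draw["bottleneck_frac"] * n_ef, 1.0)
                r = math.log(n_ef / n_b) / t0  # forward growth rate
                for d in MODEL1_DEMES:
                    demes[d] = [Epoch(0.0, n_ef, -r), Epoch(t0, n_b, 0.0)]
            demes[ANCESTRAL] = [Epoch(0.0, draw["N_anc"])]
            return Demography(demes=demes, merges=[(t1, MODEL1_DEMES, ANCESTRAL)])

        # models 2A / 2B
        t1 = gens(draw["T_split"])
        demes = {
            "eurasia": [Epoch(0.0, draw["N_eurasia"])],
            "north_america": [Epoch(0.0, draw["N_america"])],
            ANCESTRAL: [Epoch(0.0, draw["N_anc"])],
        }
        migration = None
        if self.model_id == "2B":
            m = draw["mig_rate"]
            # forward gene flow eurasia -> north_america: backwards, lineages
            # in north_america jump to eurasia
            rates = np.zeros((2, 2))
            rates[1, 0] = m
            migration = MigrationSpec(("eurasia", "north_america"), rates, active_until=t1)
        return Demography(
            demes=demes, merges=[(t1, MODEL2_DEMES, ANCESTRAL)], migration=migration
        )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        params = {}
        for k, v in self.params.items():
            if isinstance(v, UniformPrior):
                params[k] = {"prior": [v.lower, v.upper]}
            else:
                params[k] = {"value": float(v)}
        return {
            "model_id": self.model_id,
            "generation_time": self.generation_time,
            "params": params,
            "mutation": self.mutation.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioSpec":
        params: dict[str, UniformPrior | float] = {}
        for k, v in d["params"].items():
            if "prior" in v:
                params[k] = UniformPrior(*v["prior"])
            else:
                params[k] = float(v["value"])
        return cls(
            model_id=d["model_id"],
            params=params,
            generation_time=d.get("generation_time", DEFAULT_GENERATION_TIME),
            mutation=MutationModel.from_dict(d["mutation"]) if "mutation" in d else None,
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "ScenarioSpec":
        try:
            import os

            is_path = os.path.exists(str(source))
        except (TypeError, ValueError):
            is_path = False
        if is_path:
            with open(source, encoding="utf-8") as fh:
                return cls.from_dict(json.load(fh))
        return cls.from_dict(json.loads(source))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScenarioSpec):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def __repr__(self) -> str:
        return f"<ScenarioSpec {self.model_id} free={self.free_params}>"


def sample_from_priors(
    scenario: ScenarioSpec, seed: np.random.Generator | int
) -> dict[str, float]:
    """Draw a structurally valid parameter set from the scenario's priors."""
    return scenario.sample_params(seed)


def build_scenario(
    model_id: str,
    params: Mapping[str, UniformPrior | float] | None = None,
    generation_time: float = DEFAULT_GENERATION_TIME,
    mutation: MutationModel | None = None,
) -> ScenarioSpec:
    """Construct one of the stock scenarios, with default priors filled in.

    ``params`` may override any subset of the model's parameters with a
    fixed value or a different :class:`UniformPrior`.
    """
    if model_id not in _MODEL_PARAMS:
        raise ValueError(f"unknown model_id {model_id!r} (use ScenarioSpec for custom models)")
    merged: dict[str, UniformPrior | float] = dict(DEFAULT_PRIORS[model_id])
    if params:
        unknown = set(params) - set(merged)
        if unknown:
            raise ValueError(f"unknown parameters for model {model_id}: {sorted(unknown)}")
        merged.update(params)
    return ScenarioSpec(model_id, merged, generation_time=generation_time, mutation=mutation)
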