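"""Pseudo-observed datasets with the structure of the mammoth mtDNA study.

The generator emulates a Holarctic heterochronous sample: a few hundred
(default 60 at desk scale, 320 at full scale) control-region sequences of
741 bp partitioned into three mtDNA clades / geographic demes, with
calibrated ages spanning roughly 200 kyr BP down to 4 kyr BP.  Ages are
plain uniform per deme by default — the radiocarbon-limited age spectrum
and clade-replacement truncations of the real dataset are deliberately not
reproduced, but per-deme age ranges are configurable.

Truth parameters default to the headline demographic history: a three-way
split at 196 kyr BP with a shared bottleneck-and-expansion at 121 kyr BP
(model 1B), or a two-population divergence at 66 kyr BP (model 2A).  Sizes
the study does not pin down are set once here: per-deme N_ef = 20 000
(matching the inferred pre-decline female effective size), ancestral
N_anc = 5 000 and bottleneck fraction 0.05 (a structured, expansion-signal
bearing history).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .coalsim import SampleDesign, SampleTip, simulate_genealogy
from .data import HeterochronousAlignment, write_dataset
from .demography import (
    DEFAULT_GENERATION_TIME,
    MODEL1_DEMES,
    MODEL2_DEMES,
    ScenarioSpec,
    build_scenario,
)
from .mutation import DEFAULT_L, MutationModel, apply_mutations

__all__ = [
    "StudyEmulationConfig",
    "mammoth_like_design",
    "default_truth",
    "generate_pseudo_observed",
]

FAMILY_AGE_RANGE = {1: (4_000.0, 200_000.0), 2: (4_000.0, 60_000.0)}

_TRUTHS: dict[str, dict[str, float]] = {
    "1A": {"N_ef": 20_000.0, "N_anc": 5_000.0, "T_split": 196_000.0},
    "1B": {
        "N_ef": 20_000.0,
        "N_anc": 5_000.0,
        "T_split": 196_000.0,
        "T_growth": 121_000.0,
        "bottleneck_frac": 0.05,
    },
    "2A": {
        "N_eurasia": 20_000.0,
        "N_america": 5_000.0,
        "N_anc": 5_000.0,
        "T_split": 66_000.0,
    },
    "2B": {
        "N_eurasia": 20_000.0,
        "N_america": 5_000.0,
        "N_anc": 5_000.0,
        "T_split": 66_000.0,
        "mig_rate": 0.001,
    },
}


def default_truth(model_id: str) -> dict[str, float]:
    """The stock planted-truth parameter set for a model."""
    return dict(_TRUTHS[model_id])


def mammoth_like_design(
    n: int,
    model_family: int,
    seed: int | np.random.Generator,
    generation_time: float = DEFAULT_GENERATION_TIME,
    age_range: tuple[float, float] | None = None,
    proportions: Mapping[str, float] | None = None,
) -> SampleDesign:
    """A heterochronous sampling design shaped like the mammoth dataset.

    Family 1 uses three demes (``europe``, ``siberia``, ``america``), family
    2 two demes (``eurasia``, ``north_america``); ages are uniform on the
    family's default range (4-200 kyr BP and 4-60 kyr BP respectively).
    """
    if n < 6:
        raise ValueError("need n >= 6 samples")
    if model_family not in (1, 2):
        raise ValueError("model_family must be 1 or 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    demes = MODEL1_DEMES if model_family == 1 else MODEL2_DEMES
    lo, hi = age_range if age_range is not None else FAMILY_AGE_RANGE[model_family]
    if proportions is None:
        proportions = {d: 1.0 / len(demes) for d in demes}
    total = sum(proportions.values())
    counts = {d: int(round(n * proportions[d] / total)) for d in demes}
    # fix rounding drift on the last deme
    counts[demes[-1]] += n - sum(counts.values())

    ages_years = []
    labels = []
    for d in demes:
        ages_years.extend(rng.uniform(lo, hi, size=counts[d]))
        labels.extend([d] * counts[d])
    ages_years = np.array(ages_years)
    offset = float(ages_years.min())
    tips = [
        SampleTip(
            id=f"s{i:04d}",
            deme=labels[i],
            age=(ages_years[i] - offset) / generation_time,
            age_years=float(ages_years[i]),
        )
        for i in range(n)
    ]
    design = SampleDesign(tips)
    design.time_offset_years = offset
    return design


@dataclass
class StudyEmulationConfig:
    """Configuration of one pseudo-observed dataset."""

    model_id: str = "1B"
    n_samples: int = 60
    L: int = DEFAULT_L
    generation_time: float = DEFAULT_GENERATION_TIME
    truth: dict[str, float] = field(default_factory=dict)
    age_range: tuple[float, float] | None = None
    proportions: dict[str, float] | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 6:
            raise ValueError("n_samples must be >= 6")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        full = default_truth(self.model_id)
        full.update(self.truth)
        self.truth = full

    @property
    def model_family(self) -> int:
        return 1 if self.model_id in ("1A", "1B") else 2

    def scenario(self) -> ScenarioSpec:
        """The truth scenario: all parameters fixed at their planted values."""
        mut = MutationModel(
            mu=0.0956e-6 * self.generation_time
            if self.truth.get("mu") is None
            else self.truth["mu"],
            L=self.L,
        )
        params = {k: v for k, v in self.truth.items() if k != "mu"}
        return build_scenario(
            self.model_id, params=params, generation_time=self.generation_time, mutation=mut
        )


def generate_pseudo_observed(
    config: StudyEmulationConfig,
    out_fasta=None,
    out_meta=None,
    out_truth=None,
) -> tuple[HeterochronousAlignment, dict]:
    """Simulate one dataset under the planted truth; optionally write files.

    Returns the alignment and a truth record holding every realized
    parameter (for recovery scoring).  With a fixed ``master_seed`` the
    output files are byte-identical across runs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 0]))
    design = mammoth_like_design(
        config.n_samples,
        config.model_family,
        rng,
        generation_time=config.generation_time,
        age_range=config.age_range,
        proportions=config.proportions,
    )
    scenario = config.scenario()
    demog = scenario.realize(config.truth, time_offset_years=design.time_offset_years)
    genealogy = simulate_genealogy(demog, design, rng)
    alignment = apply_mutations(genealogy, scenario.mutation, rng)
    truth_record = {
        "model_id": config.model_id,
        "generation_time": config.generation_time,
        "L": config.L,
        "n_samples": config.n_samples,
        "master_seed": config.master_seed,
        "time_offset_years": design.time_offset_years,
        "params": {k: float(v) for k, v in config.truth.items()},
    }
    if out_fasta is not None and out_meta is not None:
        write_dataset(alignment, out_fasta, out_meta)
    if out_truth is not None:
        with open(out_truth, "w", encoding="utf-8") as fh:
            json.dump(truth_record, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return alignment, truth_record
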