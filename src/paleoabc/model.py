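"""Model/Results layer: ABC inference presented statsmodels-style.

:class:`DemographicABC` binds an observed heterochronous alignment to a
demographic scenario; :meth:`DemographicABC.fit` runs the simulate -> reject
-> adjust pipeline and returns a :class:`DemographicABCResults` carrying the
posterior sample, per-parameter medians with 95% credibility intervals, and
a ``summary()`` table.  :class:`ModelComparisonABC` fits several candidate
scenarios to the same data and reports posterior model probabilities and
Bayes factors by both the rejection-count and multinomial-logistic routes.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import abc as abc_engine
from .abc import (
    ModelChoiceResult,
    PosteriorSample,
    PosteriorSummary,
    ReferenceTable,
    abc_reject,
    build_reference_table,
    loclinear_adjust,
    model_posteriors,
    neuralnet_adjust,
    posterior_summary,
)
from .coalsim import SampleDesign
from .data import HeterochronousAlignment, read_dataset
from .demography import ScenarioSpec
from .sumstats import StatVector, compute_stat_vector

__all__ = ["DemographicABC", "DemographicABCResults", "ModelComparisonABC", "ModelComparisonResults"]


class DemographicABC:
    """ABC fit of a demographic scenario to a heterochronous mtDNA alignment.

    Parameters
    ----------
    data:
        The observed alignment (with ages in calendar years BP and deme
        labels matching the scenario's demes).
    scenario:
        The demographic model, with free parameters bound to priors.
    extended_stats:
        Use the extended feature panel (adds mean and minimum between-deme
        pairwise differences).  On by default: the minimum between-population
        distance is the low-variance dating statistic for split times and
        markedly improves their identifiability from a single locus.
    """

    def __init__(
        self,
        data: HeterochronousAlignment,
        scenario: ScenarioSpec,
        extended_stats: bool = True,
    ):
        missing = set(data.demes) - set(scenario.deme_ids)
        if scenario.deme_ids and missing:
            raise ValueError(
                f"data contains demes unknown to model {scenario.model_id}: {sorted(missing)}"
            )
        if data.L != scenario.mutation.L:
            raise ValueError(
                f"alignment length {data.L} != scenario mutation model L={scenario.mutation.L}"
            )
        self.data = data
        self.scenario = scenario
        self.extended_stats = extended_stats
        self.design = SampleDesign.from_alignment(data, scenario.generation_time)
        self.observed_stats: StatVector = compute_stat_vector(data, extended=extended_stats)

    @classmethod
    def from_files(cls, fasta_path, metadata_path, scenario_path, **kwargs) -> "DemographicABC":
        return cls(
            read_dataset(fasta_path, metadata_path),
            ScenarioSpec.from_json(scenario_path),
            **kwargs,
        )

    def simulate(self, n_iter: int, seed: int, progress: bool = False) -> ReferenceTable:
        """Build the prior-predictive reference table for this model/data."""
        return build_reference_table(
            self.scenario,
            self.design,
            n_iter,
            master_seed=seed,
            progress=progress,
            extended_stats=self.extended_stats,
        )

    def fit(
        self,
        n_iter: int = 50_000,
        tolerance: float = 0.01,
        method: str = "neuralnet",
        seed: int = 0,
        table: ReferenceTable | None = None,
        progress: bool = False,
        **adjust_kwargs,
    ) -> "DemographicABCResults":
        """Run ABC and return a results object.

        ``method`` is one of ``rejection``, ``loclinear``, ``neuralnet``.
        A prebuilt reference ``table`` may be supplied to re-fit at a
        different tolerance or method without re-simulating.
        """
        if method not in ("rejection", "loclinear", "neuralnet"):
            raise ValueError(f"unknown method {method!r}")
        if table is None:
            table = self.simulate(n_iter, seed, progress=progress)
        accepted = abc_reject(table, self.observed_stats, tolerance)
        if method == "loclinear":
            posterior = loclinear_adjust(accepted)
        elif method == "neuralnet":
            posterior = neuralnet_adjust(accepted, seed=seed, **adjust_kwargs)
        else:
            posterior = accepted
        return DemographicABCResults(self, table, posterior)


class DemographicABCResults:
    """Posterior estimates, uncertainties and diagnostics from one ABC fit."""

    def __init__(
        self, model: DemographicABC, table: ReferenceTable, posterior: PosteriorSample
    ):
        self.model = model
        self.table = table
        self.posterior = posterior
        self._summary: PosteriorSummary = posterior_summary(posterior)

    @property
    def params(self) -> pd.Series:
        """Posterior medians in natural units (years BP / individuals)."""
        return self._summary.table["median"].copy()

    @property
    def summary_table(self) -> pd.DataFrame:
        """Median and 95% CI per parameter, as a DataFrame."""
        return self._summary.table.copy()

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        s = posterior_summary(self.posterior, alpha=alpha).table
        return s[["ci_low", "ci_high"]].copy()

    @property
    def n_accepted(self) -> int:
        return self.posterior.n

    def summary(self) -> str:
        s = self._summary.table
        lines = [
            "ABC posterior summary",
            "=" * 58,
            f"model:            {self.model.scenario.model_id}",
            f"samples:          {self.model.data.n} sequences, L={self.model.data.L}",
            f"simulations:      {self.table.n}",
            f"tolerance:        {self.posterior.tolerance} "
            f"({self.posterior.n} accepted)",
            f"adjustment:       {self.posterior.method}"
            + (f" (fallback: {self.posterior.fallback})" if self.posterior.fallback else ""),
            "-" * 58,
            f"{'parameter':<18}{'median':>12}{'2.5%':>12}{'97.5%':>12}",
        ]
        for name, row in s.iterrows():
            lines.append(
                f"{name:<18}{row['median']:>12.5g}{row['ci_low']:>12.5g}{row['ci_high']:>12.5g}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot_posterior(self, param: str, ax=None, bins: int = 40):
        """Weighted posterior histogram with median and 95% CI markers."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        j = self.posterior.param_names.index(param)
        ax.hist(
            self.posterior.params[:, j],
            bins=bins,
            weights=self.posterior.weights,
            density=True,
            alpha=0.7,
        )
        row = self._summary.table.loc[param]
        ax.axvline(row["median"], color="k", lw=1.5)
        ax.axvline(row["ci_low"], color="k", lw=1.0, ls="--")
        ax.axvline(row["ci_high"], color="k", lw=1.0, ls="--")
        ax.set_xlabel(param)
        ax.set_ylabel("posterior density")
        return ax


class ModelComparisonResults:
    """Bayes factors and model probabilities from a multi-scenario fit."""

    def __init__(self, choice: ModelChoiceResult, tables: Sequence[ReferenceTable]):
        self.choice = choice
        self.tables = list(tables)

    @property
    def probabilities(self) -> pd.DataFrame:
        d = {"rejection": self.choice.prob_rejection}
        if self.choice.prob_mnlogit is not None:
            d["mnlogit"] = self.choice.prob_mnlogit
        return pd.DataFrame(d, index=list(self.choice.model_ids))

    def bayes_factor(self, a: str, b: str, method: str = "rejection"):
        return self.choice.bayes_factor(a, b, method=method)

    def summary(self) -> str:
        return self.choice.summary()


class ModelComparisonABC:
    """Compare candidate demographic scenarios on one observed dataset."""

    def __init__(
        self,
        data: HeterochronousAlignment,
        scenarios: Sequence[ScenarioSpec],
        extended_stats: bool = True,
    ):
        if len(scenarios) < 2:
            raise ValueError("model comparison requires at least two scenarios")
        demes0 = scenarios[0].deme_ids
        for sc in scenarios[1:]:
            if sc.deme_ids != demes0:
                raise ValueError("scenarios must share the sample design (same demes)")
        self.data = data
        self.scenarios = list(scenarios)
        self.models = [DemographicABC(data, sc, extended_stats) for sc in self.scenarios]

    def fit(
        self,
        n_iter: int = 50_000,
        tolerance: float = 0.01,
        seed: int = 0,
        tables: Sequence[ReferenceTable] | None = None,
        progress: bool = False,
    ) -> ModelComparisonResults:
        if tables is None:
            tables = [
                m.simulate(n_iter, seed + i, progress=progress)
                for i, m in enumerate(self.models)
            ]
        observed = self.models[0].observed_stats
        choice = model_posteriors(tables, observed, tolerance=tolerance, seed=seed)
        return ModelComparisonResults(choice, tables)
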