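"""ABC rejection, regression adjustments, model choice and posterior summaries.

The rejection step standardises every summary-statistic coordinate by its
median absolute deviation across the reference table (robust scaling; zero-
MAD and masked coordinates are dropped), measures Euclidean distance to the
observed vector, and keeps the ``ceil(tolerance * n)`` nearest draws.

Two regression adjustments operate on the accepted draws:

* local linear regression (Beaumont-style): weighted linear regression of
  each parameter on the statistics with Epanechnikov weights over distance,
  adjusted draws ``theta* = theta - b'(s - s_obs)``;
* a single-hidden-layer feed-forward network (Blum-Francois style) giving
  the nonlinear conditional expectation, with the elementwise median of the
  adjusted draws over independent restarts.

Model choice reports both the rejection-count Bayes factor under a common
pooled distance threshold and a multinomial-logistic estimate of posterior
model probabilities near the observed data.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import median_abs_deviation

from .coalsim import SampleDesign, simulate_genealogy
from .demography import ScenarioSpec
from .mutation import apply_mutations
from .sumstats import StatVector, compute_stat_vector

__all__ = [
    "ReferenceTable",
    "PosteriorSample",
    "PosteriorSummary",
    "ModelChoiceResult",
    "build_reference_table",
    "abc_reject",
    "loclinear_adjust",
    "neuralnet_adjust",
    "model_posteriors",
    "posterior_summary",
    "weighted_quantile",
]


# ---------------------------------------------------------------------------
# reference table
# ---------------------------------------------------------------------------


@dataclass
class ReferenceTable:
    """Parameter draws paired with summary-statistic vectors for one model."""

    model_id: str
    param_names: tuple[str, ...]
    params: np.ndarray  # (n_iter, n_params), natural units
    stat_names: tuple[str, ...]
    stats: np.ndarray  # (n_iter, n_stats); masked cells encoded as 0
    mask: np.ndarray  # (n_iter, n_stats) bool, True = undefined
    master_seed: int | None = None
    # per-parameter prior box (lo, hi), or None for fixed parameters;
    # regression adjustments use it to work on a logit scale
    param_bounds: tuple | None = None

    def __post_init__(self) -> None:
        if not (self.params.shape[0] == self.stats.shape[0] == self.mask.shape[0]):
            raise ValueError("row counts of params, stats and mask must agree")
        if np.isnan(self.stats[~self.mask]).any():
            raise ValueError("NaN in unmasked statistic cells")

    @property
    def n(self) -> int:
        return self.params.shape[0]

    def to_tsv(self, path, sidecar: bool = True) -> None:
        df = pd.DataFrame(
            np.hstack([self.params, self.stats]),
            columns=list(self.param_names) + list(self.stat_names),
        )
        df.to_csv(path, sep="\t", index=False)
        if sidecar:
            meta = {
                "model_id": self.model_id,
                "param_names": list(self.param_names),
                "stat_names": list(self.stat_names),
                "master_seed": self.master_seed,
                "param_bounds": [
                    list(b) if b is not None else None for b in (self.param_bounds or [])
                ]
                or None,
                "n": int(self.n),
                "mask_columns": [
                    list(map(int, np.flatnonzero(self.mask[:, j])))
                    for j in range(self.mask.shape[1])
                ],
            }
            with open(str(path) + ".json", "w", encoding="utf-8") as fh:
                json.dump(meta, fh)

    @classmethod
    def read_tsv(cls, path) -> "ReferenceTable":
        with open(str(path) + ".json", encoding="utf-8") as fh:
            meta = json.load(fh)
        df = pd.read_csv(path, sep="\t")
        p = len(meta["param_names"])
        params = df.iloc[:, :p].to_numpy(float)
        stats = df.iloc[:, p:].to_numpy(float)
        mask = np.zeros_like(stats, dtype=bool)
        for j, rows in enumerate(meta["mask_columns"]):
            mask[rows, j] = True
        return cls(
            model_id=meta["model_id"],
            param_names=tuple(meta["param_names"]),
            params=params,
            stat_names=tuple(meta["stat_names"]),
            stats=stats,
            mask=mask,
            master_seed=meta["master_seed"],
            param_bounds=(
                tuple(tuple(b) if b is not None else None for b in meta["param_bounds"])
                if meta.get("param_bounds")
                else None
            ),
        )


def simulate_stat_vector(
    scenario: ScenarioSpec,
    design: SampleDesign,
    draw: Mapping[str, float],
    rng: np.random.Generator,
    extended_stats: bool = False,
) -> StatVector:
    """One pipeline pass: realize -> genealogy -> mutations -> statistics."""
    demog = scenario.realize(draw, time_offset_years=design.time_offset_years)
    genealogy = simulate_genealogy(demog, design, rng)
    alignment = apply_mutations(genealogy, scenario.mutation, rng)
    return compute_stat_vector(alignment, extended=extended_stats)


def build_reference_table(
    scenario: ScenarioSpec,
    design: SampleDesign,
    n_iter: int,
    master_seed: int,
    progress: bool = False,
    extended_stats: bool = False,
) -> ReferenceTable:
    """Run ``n_iter`` prior-predictive simulations for one scenario.

    Row ``i`` is reproducible in isolation from ``(master_seed, i)``, so a
    table can be built in parallel chunks with identical results.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    param_names = tuple(scenario.params)
    params = np.empty((n_iter, len(param_names)))
    stats = None
    mask = None
    stat_names: tuple[str, ...] = ()
    for i in range(n_iter):
        rng = np.random.default_rng(np.random.SeedSequence([master_seed, i]))
        try:
            draw = scenario.sample_params(rng)
            sv = simulate_stat_vector(scenario, design, draw, rng, extended_stats)
        except Exception as exc:  # noqa: BLE001 - annotate row and re-raise
            raise RuntimeError(f"simulation failed at table row {i}: {exc}") from exc
        if stats is None:
            stat_names = sv.names
            stats = np.empty((n_iter, len(sv)))
            mask = np.zeros((n_iter, len(sv)), dtype=bool)
        params[i] = [draw[k] for k in param_names]
        stats[i] = sv.values
        mask[i] = sv.mask
        if progress and (i + 1) % 1000 == 0:
            print(f"  reference table {scenario.model_id}: {i + 1}/{n_iter}", flush=True)
    from .demography import UniformPrior

    bounds = tuple(
        (v.lower, v.upper) if isinstance(v, UniformPrior) else None
        for v in scenario.params.values()
    )
    return ReferenceTable(
        model_id=scenario.model_id,
        param_names=param_names,
        params=params,
        stat_names=stat_names,
        stats=stats,
        mask=mask,
        master_seed=master_seed,
        param_bounds=bounds,
    )


# ---------------------------------------------------------------------------
# rejection
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSample:
    """Accepted (possibly regression-adjusted) draws with weights."""

    param_names: tuple[str, ...]
    params: np.ndarray  # (m, n_params)
    weights: np.ndarray  # non-negative, sum to 1
    method: str  # rejection | loclinear | neuralnet
    tolerance: float
    # standardized accepted statistics and observed vector over used coords,
    # retained so regression adjustments can operate on the sample
    stats_std: np.ndarray | None = None
    s_obs_std: np.ndarray | None = None
    distances: np.ndarray | None = None
    used_stat_names: tuple[str, ...] = ()
    fallback: str | None = None
    param_bounds: tuple | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("weights must not all be zero")
        self.weights = w / total

    @property
    def n(self) -> int:
        return self.params.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.params, columns=list(self.param_names))
        df["weight"] = self.weights
        return df


def _usable_coordinates(
    table: ReferenceTable, observed: StatVector
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of coordinates usable for distances, and their MAD scales.

    A coordinate is dropped when masked in the observed vector or when its
    MAD across the (unmasked) table rows is zero; mask bits must refer to the
    same ordering in observed and simulated vectors.
    """
    if tuple(observed.names) != tuple(table.stat_names):
        raise ValueError("observed statistics ordering differs from the table's")
    mads = median_abs_deviation(table.stats, axis=0, nan_policy="omit")
    usable = (~observed.mask) & (mads > 0)
    if not usable.any():
        raise ValueError("no usable statistic coordinates (all masked or constant)")
    # drop coordinates that duplicate an earlier one up to an affine map
    # (e.g. mean pairwise differences vs per-site diversity, which differ
    # only by 1/L): they double-count in the distance and make the
    # regression designs singular
    idx = np.flatnonzero(usable)
    std = table.stats[:, idx] / mads[idx]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(std.T)
    kept_local: list[int] = []
    for j in range(len(idx)):
        if all(abs(corr[j, i]) < 1 - 1e-10 for i in kept_local):
            kept_local.append(j)
    kept = idx[kept_local]
    return kept, mads[kept]


def abc_reject(
    table: ReferenceTable, observed: StatVector, tolerance: float
) -> PosteriorSample:
    """Keep the ``ceil(tolerance * n)`` draws nearest to the observed vector."""
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must lie in (0, 1]")
    idx, scales = _usable_coordinates(table, observed)
    stats_std = table.stats[:, idx] / scales
    s_obs_std = observed.values[idx] / scales
    dist = np.sqrt(((stats_std - s_obs_std) ** 2).sum(axis=1))
    m = math.ceil(tolerance * table.n)
    order = np.argsort(dist, kind="stable")[:m]
    return PosteriorSample(
        param_names=table.param_names,
        params=table.params[order].copy(),
        weights=np.full(m, 1.0 / m),
        method="rejection",
        tolerance=tolerance,
        stats_std=stats_std[order],
        s_obs_std=s_obs_std,
        distances=dist[order],
        used_stat_names=tuple(np.asarray(table.stat_names)[idx]),
        param_bounds=table.param_bounds,
    )


# ---------------------------------------------------------------------------
# regression adjustments
# ---------------------------------------------------------------------------


_LOGIT_EPS = 1e-9


def _to_adjust_scale(params: np.ndarray, bounds) -> np.ndarray:
    """Map prior-bounded parameters to a logit scale for regression.

    Keeps regression-adjusted draws inside their prior box after the inverse
    map; unbounded (fixed) parameters pass through unchanged.
    """
    out = params.astype(float).copy()
    if bounds is None:
        return out
    for j, b in enumerate(bounds):
        if b is None:
            continue
        lo, hi = b
        u = np.clip((out[:, j] - lo) / (hi - lo), _LOGIT_EPS, 1 - _LOGIT_EPS)
        out[:, j] = np.log(u / (1 - u))
    return out


def _from_adjust_scale(z: np.ndarray, bounds) -> np.ndarray:
    out = z.astype(float).copy()
    if bounds is None:
        return out
    for j, b in enumerate(bounds):
        if b is None:
            continue
        lo, hi = b
        out[:, j] = lo + (hi - lo) / (1.0 + np.exp(-out[:, j]))
    return out


def _epanechnikov(distances: np.ndarray) -> np.ndarray:
    d_max = distances.max()
    if d_max == 0:
        return np.ones_like(distances)
    w = 1.0 - (distances / d_max) ** 2
    # the furthest accepted point would get weight 0; keep it marginally in
    return np.maximum(w, 1e-12)


def _independent_columns(X: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (pivoted QR).

    Summary statistics can be exactly linearly dependent (the pooled mean
    pairwise difference is a fixed combination of the within- and
    between-group means); redundant columns carry no extra information and
    would make the regression design singular.
    """
    from scipy.linalg import qr

    if X.shape[1] == 0:
        return np.zeros(0, dtype=int)
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0 or diag[0] == 0:
        return np.zeros(0, dtype=int)
    rank = int((diag > rtol * diag[0]).sum())
    return np.sort(piv[:rank])


def loclinear_adjust(accepted: PosteriorSample) -> PosteriorSample:
    """Beaumont-style local-linear regression adjustment of accepted draws."""
    if accepted.stats_std is None:
        raise ValueError("accepted sample does not carry its statistics")
    X = accepted.stats_std - accepted.s_obs_std
    # drop coordinates with no variation among the accepted draws
    keep = X.std(axis=0) > 0
    w = _epanechnikov(accepted.distances)
    if not keep.any():
        return PosteriorSample(
            param_names=accepted.param_names,
            params=accepted.params.copy(),
            weights=w,
            method="loclinear",
            tolerance=accepted.tolerance,
            stats_std=accepted.stats_std,
            s_obs_std=accepted.s_obs_std,
            distances=accepted.distances,
            used_stat_names=accepted.used_stat_names,
        )
    Xk = X[:, keep]
    Xk = Xk[:, _independent_columns(Xk)]
    if accepted.n < Xk.shape[1] + 2:
        raise ValueError("need more accepted draws than statistics for the regression")
    Y = _to_adjust_scale(accepted.params, accepted.param_bounds)
    A = np.hstack([np.ones((accepted.n, 1)), Xk])
    sw = np.sqrt(w)[:, None]
    coef, _, rank, _ = np.linalg.lstsq(A * sw, Y * sw, rcond=None)
    if rank < A.shape[1]:
        warnings.warn(
            "singular local-linear design; falling back to rejection", stacklevel=2
        )
        return PosteriorSample(
            param_names=accepted.param_names,
            params=accepted.params.copy(),
            weights=accepted.weights,
            method="rejection",
            tolerance=accepted.tolerance,
            stats_std=accepted.stats_std,
            s_obs_std=accepted.s_obs_std,
            distances=accepted.distances,
            used_stat_names=accepted.used_stat_names,
            fallback="singular-design",
            param_bounds=accepted.param_bounds,
        )
    beta = coef[1:]
    adjusted = _from_adjust_scale(Y - Xk @ beta, accepted.param_bounds)
    return PosteriorSample(
        param_names=accepted.param_names,
        params=adjusted,
        weights=w,
        method="loclinear",
        tolerance=accepted.tolerance,
        stats_std=accepted.stats_std,
        s_obs_std=accepted.s_obs_std,
        distances=accepted.distances,
        used_stat_names=accepted.used_stat_names,
        param_bounds=accepted.param_bounds,
    )


def _fit_mlp(
    X: np.ndarray,
    Y: np.ndarray,
    w: np.ndarray,
    hidden: int,
    epochs: int,
    rng: np.random.Generator,
    decay: float = 1e-3,
) -> tuple[callable, bool]:
    """Weighted single-hidden-layer (tanh) least-squares network via L-BFGS."""
    m, k = X.shape
    p = Y.shape[1]
    sizes = [(k, hidden), (hidden,), (hidden, p), (p,)]
    splits = np.cumsum([int(np.prod(s)) for s in sizes])[:-1]
    wsum = w.sum()

    def unpack(theta):
        parts = np.split(theta, splits)
        return [part.reshape(s) for part, s in zip(parts, sizes)]

    def loss_grad(theta):
        W1, b1, W2, b2 = unpack(theta)
        Z = X @ W1 + b1
        H = np.tanh(Z)
        P = H @ W2 + b2
        E = P - Y
        L = float((w[:, None] * E**2).sum() / wsum + decay * ((W1**2).sum() + (W2**2).sum()))
        Gp = 2.0 * w[:, None] * E / wsum
        dW2 = H.T @ Gp + 2 * decay * W2
        db2 = Gp.sum(axis=0)
        dZ = (Gp @ W2.T) * (1.0 - H**2)
        dW1 = X.T @ dZ + 2 * decay * W1
        db1 = dZ.sum(axis=0)
        grad = np.concatenate([dW1.ravel(), db1.ravel(), dW2.ravel(), db2.ravel()])
        return L, grad

    theta0 = rng.normal(0.0, 0.5, size=splits[-1] + p)
    res = optimize.minimize(
        loss_grad, theta0, jac=True, method="L-BFGS-B", options={"maxiter": epochs}
    )
    W1, b1, W2, b2 = unpack(res.x)

    def predict(Xnew: np.ndarray) -> np.ndarray:
        return np.tanh(Xnew @ W1 + b1) @ W2 + b2

    return predict, bool(res.success or res.fun < loss_grad(theta0)[0])


def neuralnet_adjust(
    accepted: PosteriorSample,
    hidden_units: int = 4,
    epochs: int = 500,
    replicates: int = 5,
    seed: int = 0,
) -> PosteriorSample:
    """Neural-network regression adjustment (median over restarts).

    With ``hidden_units=0`` the network degenerates to a linear map and the
    result is exactly the local-linear adjustment.  If no restart converges
    the function falls back to the local-linear adjustment with a flag.
    """
    if hidden_units == 0:
        return loclinear_adjust(accepted)
    if accepted.stats_std is None:
        raise ValueError("accepted sample does not carry its statistics")
    X = accepted.stats_std - accepted.s_obs_std
    keep = X.std(axis=0) > 0
    w = _epanechnikov(accepted.distances)
    if not keep.any():
        out = loclinear_adjust(accepted)
        out.method = "neuralnet"
        return out
    Xk = X[:, keep]
    # regress on the logit scale, standardised; adjust, then map back
    Yt = _to_adjust_scale(accepted.params, accepted.param_bounds)
    y_loc = Yt.mean(axis=0)
    y_scale = Yt.std(axis=0)
    y_scale[y_scale == 0] = 1.0
    Y = (Yt - y_loc) / y_scale

    adjusted_reps = []
    for r in range(replicates):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        predict, ok = _fit_mlp(Xk, Y, w, hidden_units, epochs, rng)
        if not ok:
            continue
        resid = Y - predict(Xk)
        cond = predict(np.zeros((1, Xk.shape[1])))[0]  # s = s_obs maps to X = 0
        adjusted_reps.append((cond + resid) * y_scale + y_loc)
    if not adjusted_reps:
        warnings.warn("no neural-net restart converged; falling back", stacklevel=2)
        out = loclinear_adjust(accepted)
        out.fallback = "neuralnet-nonconvergence"
        return out
    adjusted = _from_adjust_scale(np.median(adjusted_reps, axis=0), accepted.param_bounds)
    return PosteriorSample(
        param_names=accepted.param_names,
        params=adjusted,
        weights=w,
        method="neuralnet",
        tolerance=accepted.tolerance,
        stats_std=accepted.stats_std,
        s_obs_std=accepted.s_obs_std,
        distances=accepted.distances,
        used_stat_names=accepted.used_stat_names,
        param_bounds=accepted.param_bounds,
    )


# ---------------------------------------------------------------------------
# model choice
# ---------------------------------------------------------------------------


@dataclass
class ModelChoiceResult:
    """Posterior model probabilities and pairwise Bayes factors, both methods."""

    model_ids: tuple[str, ...]
    counts: np.ndarray  # accepted counts per model under the pooled threshold
    prob_rejection: np.ndarray
    prob_mnlogit: np.ndarray | None
    threshold: float
    n_accepted: int

    def _bf(self, probs: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return probs[:, None] / probs[None, :]

    @property
    def bf_rejection(self) -> np.ndarray:
        return self._bf(self.prob_rejection)

    @property
    def bf_mnlogit(self) -> np.ndarray | None:
        return None if self.prob_mnlogit is None else self._bf(self.prob_mnlogit)

    def bayes_factor(self, a: str, b: str, method: str = "rejection") -> float | str:
        """BF(a, b); a bound string ``'>n'`` when model b got zero acceptances."""
        ia, ib = self.model_ids.index(a), self.model_ids.index(b)
        if method == "rejection":
            if self.counts[ib] == 0:
                return f">{int(self.counts[ia])}"
            return float(self.counts[ia] / self.counts[ib])
        probs = self.prob_mnlogit
        if probs is None:
            raise ValueError("multinomial-logistic probabilities unavailable")
        if probs[ib] == 0:
            return f">{probs[ia] / max(probs[ib], 1e-300):.3g}"
        return float(probs[ia] / probs[ib])

    def summary(self) -> str:
        lines = ["Model choice (pooled rejection threshold %.4g)" % self.threshold]
        lines.append(f"{'model':>12} {'count':>8} {'P(rej)':>8} {'P(mnlogit)':>11}")
        for i, mid in enumerate(self.model_ids):
            pm = "-" if self.prob_mnlogit is None else f"{self.prob_mnlogit[i]:.4f}"
            lines.append(
                f"{mid:>12} {int(self.counts[i]):>8} {self.prob_rejection[i]:>8.4f} {pm:>11}"
            )
        for i in range(len(self.model_ids)):
            for j in range(len(self.model_ids)):
                if i == j:
                    continue
                bf = self.bayes_factor(self.model_ids[i], self.model_ids[j])
                bf_s = bf if isinstance(bf, str) else f"{bf:.3g}"
                lines.append(f"BF({self.model_ids[i]}, {self.model_ids[j]}) = {bf_s}")
        return "\n".join(lines)


def model_posteriors(
    tables: Sequence[ReferenceTable],
    observed: StatVector,
    tolerance: float = 0.01,
    mnlogit: bool = True,
    seed: int = 0,
) -> ModelChoiceResult:
    """Posterior model probabilities from pooled-table rejection + logistic fit.

    All tables must share the statistic ordering; models carry equal prior
    probability (tables should have equal row counts for the count-based BF
    to be a Bayes factor).
    """
    if len(tables) < 2:
        raise ValueError("model choice requires at least two reference tables")
    names0 = tables[0].stat_names
    for t in tables[1:]:
        if t.stat_names != names0:
            raise ValueError("reference tables have mismatched statistic orderings")
    pooled_stats = np.vstack([t.stats for t in tables])
    labels = np.concatenate([np.full(t.n, i) for i, t in enumerate(tables)])
    pooled = ReferenceTable(
        model_id="pooled",
        param_names=("dummy",),
        params=np.zeros((pooled_stats.shape[0], 1)),
        stat_names=names0,
        stats=pooled_stats,
        mask=np.zeros_like(pooled_stats, dtype=bool),
    )
    idx, scales = _usable_coordinates(pooled, observed)
    stats_std = pooled_stats[:, idx] / scales
    s_obs_std = observed.values[idx] / scales
    dist = np.sqrt(((stats_std - s_obs_std) ** 2).sum(axis=1))
    m = math.ceil(tolerance * len(dist))
    order = np.argsort(dist, kind="stable")[:m]
    threshold = float(dist[order[-1]])
    acc_labels = labels[order]
    counts = np.array([(acc_labels == i).sum() for i in range(len(tables))], float)
    prob_rejection = counts / counts.sum()

    prob_mnlogit = None
    if mnlogit:
        if len(np.unique(acc_labels)) < 2:
            prob_mnlogit = prob_rejection.copy()
        else:
            from sklearn.linear_model import LogisticRegression

            w = _epanechnikov(dist[order])
            clf = LogisticRegression(max_iter=2000, random_state=seed)
            clf.fit(stats_std[order], acc_labels, sample_weight=w)
            raw = clf.predict_proba(s_obs_std[None, :])[0]
            prob_mnlogit = np.zeros(len(tables))
            for cls, pr in zip(clf.classes_, raw):
                prob_mnlogit[int(cls)] = pr
    return ModelChoiceResult(
        model_ids=tuple(t.model_id for t in tables),
        counts=counts,
        prob_rejection=prob_rejection,
        prob_mnlogit=prob_mnlogit,
        threshold=threshold,
        n_accepted=m,
    )


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


def weighted_quantile(
    values: np.ndarray, q: float | np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Interpolated quantiles of a weighted sample.

    Linear interpolation on the weighted empirical CDF evaluated at the
    midpoint of each atom's mass (reduces to the usual type-7-like
    interpolation for equal weights).
    """
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    pos = weights > 0
    values, weights = values[pos], weights[pos]
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    total = w.sum()
    cdf = (np.cumsum(w) - 0.5 * w) / total
    return np.interp(q, cdf, v)


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-parameter weighted median and 95% credibility interval."""

    table: pd.DataFrame  # index = parameter, columns = median, ci_low, ci_high

    def __post_init__(self) -> None:
        t = self.table
        if ((t["ci_low"] > t["median"]) | (t["median"] > t["ci_high"])).any():
            raise ValueError("quantiles out of order")

    def __getitem__(self, param: str) -> pd.Series:
        return self.table.loc[param]

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda x: f"{x:.6g}")


def posterior_summary(sample: PosteriorSample, alpha: float = 0.05) -> PosteriorSummary:
    """Weighted median and central (1 - alpha) credibility interval."""
    if sample.n == 0:
        raise ValueError("empty posterior sample")
    qs = [alpha / 2, 0.5, 1 - alpha / 2]
    rows = {}
    for j, name in enumerate(sample.param_names):
        lo, med, hi = weighted_quantile(sample.params[:, j], qs, sample.weights)
        rows[name] = {"median": med, "ci_low": lo, "ci_high": hi}
    table = pd.DataFrame(rows).T[["median", "ci_low", "ci_high"]]
    return PosteriorSummary(table)
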