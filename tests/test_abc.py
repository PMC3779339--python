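"""ABC engine: rejection bookkeeping, adjustments, model choice, summaries."""

import numpy as np
import pytest

from paleoabc.abc import (
    PosteriorSample,
    ReferenceTable,
    abc_reject,
    loclinear_adjust,
    model_posteriors,
    neuralnet_adjust,
    posterior_summary,
    weighted_quantile,
)
from paleoabc.sumstats import StatVector


def toy_table(n, rng, relation="linear", model_id="toy"):
    """Reference table with a known parameter-statistic relation."""
    s = rng.uniform(-2.0, 2.0, size=(n, 1))
    noise_col = rng.normal(size=(n, 1))  # uninformative second statistic
    if relation == "linear":
        theta = 3.0 * s[:, 0]
    else:  # quadratic
        theta = s[:, 0] ** 2
    stats = np.hstack([s, noise_col])
    return ReferenceTable(
        model_id=model_id,
        param_names=("theta",),
        params=theta[:, None],
        stat_names=("s1", "s2"),
        stats=stats,
        mask=np.zeros_like(stats, dtype=bool),
    )


def observed(values, mask=None):
    values = np.asarray(values, float)
    return StatVector(
        names=("s1", "s2"),
        values=values,
        mask=np.zeros(len(values), bool) if mask is None else np.asarray(mask),
    )


class TestRejection:
    def test_tolerance_one_accepts_everything(self, rng):
        t = toy_table(500, rng)
        post = abc_reject(t, observed([0.0, 0.0]), 1.0)
        assert post.n == 500

    def test_exact_match_accepted_at_minimal_tolerance(self, rng):
        t = toy_table(100, rng)
        obs = observed(t.stats[17])
        post = abc_reject(t, obs, 1 / 100)
        assert post.n == 1
        assert post.params[0, 0] == t.params[17, 0]
        assert post.distances[0] == 0.0

    def test_acceptance_count_bookkeeping(self, rng):
        t = toy_table(10_000, rng)
        post = abc_reject(t, observed([0.0, 0.0]), 0.01)
        assert post.n == 100

    def test_all_masked_is_error(self, rng):
        t = toy_table(50, rng)
        with pytest.raises(ValueError, match="usable"):
            abc_reject(t, observed([0.0, 0.0], mask=[True, True]), 0.1)

    def test_posterior_approaches_prior_at_full_tolerance(self, rng):
        from scipy import stats as sps

        # theta ~ U(-6, 6) via the linear map of s ~ U(-2, 2)
        t = toy_table(2000, rng)
        post = abc_reject(t, observed([0.0, 0.0]), 1.0)
        assert sps.kstest(post.params[:, 0], sps.uniform(-6, 12).cdf).pvalue > 0.01


class TestLocLinear:
    def test_exact_linear_relation_collapses(self, rng):
        t = toy_table(400, rng, relation="linear")
        s_obs = 0.7
        post = abc_reject(t, observed([s_obs, 0.0]), 0.5)
        adj = loclinear_adjust(post)
        np.testing.assert_allclose(adj.params[:, 0], 3.0 * s_obs, atol=1e-8)

    def test_identical_stats_leave_params_unchanged(self, rng):
        params = rng.normal(size=(50, 1))
        stats = np.ones((50, 2))
        post = PosteriorSample(
            param_names=("theta",),
            params=params,
            weights=np.full(50, 0.02),
            method="rejection",
            tolerance=0.1,
            stats_std=stats,
            s_obs_std=np.ones(2),
            distances=np.zeros(50),
        )
        adj = loclinear_adjust(post)
        np.testing.assert_allclose(adj.params, params)

    def test_adjustment_reduces_posterior_error_on_linear_gaussian_toy(self, rng):
        wins = 0
        for rep in range(50):
            r = np.random.default_rng(1000 + rep)
            n = 400
            theta = r.uniform(-5, 5, n)
            s = theta + r.normal(0, 0.5, n)
            table = ReferenceTable(
                "toy", ("theta",), theta[:, None], ("s",), s[:, None],
                np.zeros((n, 1), bool),
            )
            truth = 1.3
            obs = StatVector(("s",), np.array([truth]), np.zeros(1, bool))
            post = abc_reject(table, obs, 0.1)
            adj = loclinear_adjust(post)
            rmse_rej = np.sqrt(np.mean((post.params[:, 0] - truth) ** 2))
            rmse_adj = np.sqrt(np.mean((adj.params[:, 0] - truth) ** 2))
            wins += rmse_adj < rmse_rej
        assert wins > 25


class TestNeuralNet:
    def test_zero_hidden_units_equals_loclinear(self, rng):
        t = toy_table(300, rng)
        post = abc_reject(t, observed([0.5, 0.0]), 0.3)
        nn = neuralnet_adjust(post, hidden_units=0)
        ll = loclinear_adjust(post)
        np.testing.assert_allclose(nn.params, ll.params)

    def test_reproducible_under_fixed_seed(self, rng):
        t = toy_table(300, rng)
        post = abc_reject(t, observed([0.5, 0.0]), 0.3)
        a = neuralnet_adjust(post, seed=42)
        b = neuralnet_adjust(post, seed=42)
        np.testing.assert_array_equal(a.params, b.params)

    def test_quadratic_relation_beats_loclinear(self):
        s_obs = 1.5
        truth = s_obs**2
        nn_better = 0
        for rep in range(20):
            r = np.random.default_rng(2000 + rep)
            t = toy_table(600, r, relation="quadratic")
            post = abc_reject(t, observed([s_obs, 0.0]), 0.5)
            ll = loclinear_adjust(post)
            nn = neuralnet_adjust(post, hidden_units=4, replicates=3, seed=rep)
            err_ll = abs(np.median(ll.params[:, 0]) - truth)
            err_nn = abs(np.median(nn.params[:, 0]) - truth)
            nn_better += err_nn < err_ll
        assert nn_better >= 13


class TestModelChoice:
    def test_identical_tables_give_bf_near_one(self, rng):
        t1 = toy_table(3000, rng, model_id="A")
        t2 = toy_table(3000, np.random.default_rng(rng.integers(2**31)), model_id="B")
        res = model_posteriors([t1, t2], observed([0.3, 0.0]), tolerance=0.05)
        bf = res.bayes_factor("A", "B")
        assert 1 / 3 < bf < 3

    @staticmethod
    def _one_stat_table(s, mid):
        return ReferenceTable(
            mid, ("p",), np.zeros((len(s), 1)), ("s",),
            np.asarray(s, float)[:, None], np.zeros((len(s), 1), bool),
        )

    def test_count_ratio_definition(self):
        # model A puts 3x the mass of model B at the observed value
        r = np.random.default_rng(9)
        sA = np.concatenate([r.uniform(0, 1, 300), r.uniform(40, 60, 700)])
        sB = np.concatenate([r.uniform(0, 1, 100), r.uniform(40, 60, 900)])
        res = model_posteriors(
            [self._one_stat_table(sA, "A"), self._one_stat_table(sB, "B")],
            StatVector(("s",), np.array([0.0]), np.zeros(1, bool)),
            tolerance=0.2,
            mnlogit=False,
        )
        assert res.counts.sum() == 400
        assert res.bayes_factor("A", "B") == pytest.approx(3.0)

    def test_zero_count_reports_bound(self):
        res = model_posteriors(
            [
                self._one_stat_table(np.random.default_rng(3).uniform(0, 1, 100), "A"),
                self._one_stat_table(np.random.default_rng(4).uniform(98, 99, 100), "B"),
            ],
            StatVector(("s",), np.array([0.0]), np.zeros(1, bool)),
            tolerance=0.1,
            mnlogit=False,
        )
        assert res.bayes_factor("A", "B") == ">20"

    def test_mismatched_stat_orderings_rejected(self, rng):
        t1 = toy_table(100, rng, model_id="A")
        t2 = toy_table(100, rng, model_id="B")
        t2.stat_names = ("s2", "s1")
        with pytest.raises(ValueError, match="mismatch"):
            model_posteriors([t1, t2], observed([0.0, 0.0]))


class TestPosteriorSummary:
    def test_equal_weight_median(self):
        draws = np.arange(1, 101, dtype=float)[:, None]
        s = PosteriorSample(("x",), draws, np.full(100, 0.01), "rejection", 0.1)
        assert posterior_summary(s).table.loc["x", "median"] == pytest.approx(50.5)

    def test_point_mass_degenerate_ci(self):
        s = PosteriorSample(
            ("x",), np.array([[1.0], [7.0]]), np.array([0.0, 1.0]), "rejection", 0.1
        )
        row = posterior_summary(s).table.loc["x"]
        assert row["ci_low"] == row["median"] == row["ci_high"] == 7.0

    def test_uniform_quantile_consistency(self, rng):
        x = rng.uniform(0, 1, 100_000)
        w = np.full(len(x), 1 / len(x))
        lo, hi = weighted_quantile(x, [0.025, 0.975], w)
        assert lo == pytest.approx(0.025, abs=0.005)
        assert hi == pytest.approx(0.975, abs=0.005)

    def test_weighted_quantile_respects_weights(self):
        x = np.array([0.0, 10.0])
        # nearly all mass on the larger draw
        assert weighted_quantile(x, 0.5, np.array([0.01, 0.99])) > 9.0


def test_reference_table_round_trip(tmp_path, rng):
    t = toy_table(50, rng)
    t.param_bounds = ((-6.0, 6.0),)
    path = tmp_path / "table.tsv"
    t.to_tsv(path)
    back = ReferenceTable.read_tsv(path)
    assert back.model_id == t.model_id
    assert back.param_names == t.param_names
    assert back.param_bounds == ((-6.0, 6.0),)
    np.testing.assert_allclose(back.params, t.params)
    np.testing.assert_allclose(back.stats, t.stats)
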