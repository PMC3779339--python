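"""Model/Results layer and command-line interface."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from paleoabc import DemographicABC, ModelComparisonABC, build_scenario
from paleoabc.cli import main
from paleoabc.synthetic import StudyEmulationConfig, generate_pseudo_observed


@pytest.fixture(scope="module")
def pseudo_2a():
    cfg = StudyEmulationConfig(model_id="2A", n_samples=24, master_seed=8)
    return generate_pseudo_observed(cfg)


def test_fit_is_deterministic(pseudo_2a):
    aln, _ = pseudo_2a
    m = DemographicABC(aln, build_scenario("2A"))
    r1 = m.fit(n_iter=400, tolerance=0.05, method="loclinear", seed=5)
    r2 = m.fit(n_iter=400, tolerance=0.05, method="loclinear", seed=5)
    np.testing.assert_array_equal(r1.posterior.params, r2.posterior.params)
    assert (r1.params == r2.params).all()


def test_results_surface(pseudo_2a):
    aln, _ = pseudo_2a
    m = DemographicABC(aln, build_scenario("2A"))
    res = m.fit(n_iter=400, tolerance=0.05, method="rejection", seed=1)
    assert res.n_accepted == 20
    ci = res.conf_int()
    assert set(ci.columns) == {"ci_low", "ci_high"}
    assert (ci["ci_low"] <= res.params).all() and (res.params <= ci["ci_high"]).all()
    text = res.summary()
    assert "T_split" in text and "2.5%" in text
    # refit from the cached table at another tolerance
    res2 = m.fit(tolerance=0.1, method="rejection", table=res.table)
    assert res2.n_accepted == 40


def test_posterior_near_prior_at_full_tolerance(pseudo_2a):
    from scipy import stats as sps

    aln, _ = pseudo_2a
    sc = build_scenario("2A")
    m = DemographicABC(aln, sc)
    res = m.fit(n_iter=600, tolerance=1.0, method="rejection", seed=2)
    j = res.posterior.param_names.index("T_split")
    prior = sc.params["T_split"]
    ks = sps.kstest(
        res.posterior.params[:, j], sps.uniform(prior.lower, prior.upper - prior.lower).cdf
    )
    assert ks.pvalue > 0.01


def test_plot_posterior_returns_axis(pseudo_2a):
    import matplotlib

    matplotlib.use("Agg")
    aln, _ = pseudo_2a
    m = DemographicABC(aln, build_scenario("2A"))
    res = m.fit(n_iter=300, tolerance=0.1, method="rejection", seed=3)
    ax = res.plot_posterior("T_split")
    assert ax.get_xlabel() == "T_split"


def test_model_comparison_reports_both_bf_methods(pseudo_2a):
    aln, _ = pseudo_2a
    cmp = ModelComparisonABC(aln, [build_scenario("2A"), build_scenario("2B")])
    res = cmp.fit(n_iter=500, tolerance=0.05, seed=4)
    probs = res.probabilities
    assert list(probs.columns) == ["rejection", "mnlogit"]
    assert probs["rejection"].sum() == pytest.approx(1.0)
    assert probs["mnlogit"].sum() == pytest.approx(1.0, abs=1e-6)
    assert "BF(2A, 2B)" in res.summary()


def test_same_scenario_twice_gives_bf_near_one(pseudo_2a):
    # two independent tables from the identical model must split acceptances
    # roughly evenly: the count Bayes factor is 1 up to Monte-Carlo error
    aln, _ = pseudo_2a
    cmp = ModelComparisonABC(aln, [build_scenario("2A"), build_scenario("2A")])
    res = cmp.fit(n_iter=1500, tolerance=0.05, seed=6)
    counts = res.choice.counts
    assert counts.sum() == 150
    assert 1 / 3 < counts[0] / counts[1] < 3


def test_data_scenario_mismatch_rejected(pseudo_2a):
    aln, _ = pseudo_2a
    with pytest.raises(ValueError, match="demes unknown"):
        DemographicABC(aln, build_scenario("1B"))


class TestCli:
    def test_gen_data_then_sumstats_and_fit(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "ds"
        r = runner.invoke(
            main,
            ["gen-data", "--model-id", "2A", "--n", "16", "--seed", "3", "--out", str(out)],
        )
        assert r.exit_code == 0, r.output
        assert (tmp_path / "ds.fasta").exists()
        truth = json.loads((tmp_path / "ds.truth.json").read_text())
        assert truth["params"]["T_split"] == 66000.0

        r = runner.invoke(
            main,
            [
                "sumstats",
                "--observed-fasta", str(tmp_path / "ds.fasta"),
                "--observed-meta", str(tmp_path / "ds.tsv"),
                "--out", str(tmp_path / "sv.tsv"),
            ],
        )
        assert r.exit_code == 0, r.output

        r = runner.invoke(
            main,
            [
                "abc-fit",
                "--scenario", "2A",
                "--observed-fasta", str(tmp_path / "ds.fasta"),
                "--observed-meta", str(tmp_path / "ds.tsv"),
                "--n-iter", "300",
                "--tolerance", "0.05",
                "--method", "rejection",
                "--out", str(tmp_path / "fit"),
            ],
        )
        assert r.exit_code == 0, r.output
        summary = json.loads((tmp_path / "fit" / "summary.json").read_text())
        assert "T_split" in summary
        assert (tmp_path / "fit" / "posterior.tsv").exists()

    def test_recover_writes_report(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(
            main,
            [
                "recover",
                "--model-id", "2A",
                "--n", "12",
                "--n-iter", "400",
                "--tolerance", "0.05",
                "--method", "loclinear",
                "--seed", "2",
                "--out", str(tmp_path / "rec"),
            ],
        )
        assert r.exit_code == 0, r.output
        report = json.loads((tmp_path / "rec" / "recovery.json").read_text())
        assert report["T_split"]["truth"] == 66000.0
        assert "in_ci" in report["T_split"]

    def test_validation_error_exits_with_code_two(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(
            main,
            ["gen-data", "--model-id", "9Z", "--out", str(tmp_path / "x")],
        )
        assert r.exit_code == 2

    def test_model_compare_smoke(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "ds"
        runner.invoke(
            main,
            ["gen-data", "--model-id", "2A", "--n", "12", "--seed", "5", "--out", str(out)],
        )
        r = runner.invoke(
            main,
            [
                "model-compare",
                "--scenario", "2A",
                "--scenario", "2B",
                "--observed-fasta", str(tmp_path / "ds.fasta"),
                "--observed-meta", str(tmp_path / "ds.tsv"),
                "--n-iter", "300",
                "--tolerance", "0.05",
                "--out", str(tmp_path / "cmp"),
            ],
        )
        assert r.exit_code == 0, r.output
        text = (tmp_path / "cmp" / "model_choice.txt").read_text()
        assert "BF(2A, 2B)" in text
        probs = (tmp_path / "cmp" / "model_probabilities.tsv").read_text()
        assert "rejection" in probs and "mnlogit" in probs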