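"""Summary statistics against hand-computed values and invariances."""

import numpy as np
import pytest

from paleoabc.data import HeterochronousAlignment, SequenceSample
from paleoabc.sumstats import (
    compute_stat_vector,
    haplotype_diversity,
    mean_pairwise_differences,
    nucleotide_diversity,
    pairwise_fst,
    segregating_sites,
    tajimas_d,
)


def aln_of(seqs, demes=None, ages=None):
    demes = demes or ["d"] * len(seqs)
    ages = ages or [0.0] * len(seqs)
    return HeterochronousAlignment(
        [
            SequenceSample(f"s{i}", s, a, d)
            for i, (s, d, a) in enumerate(zip(seqs, demes, ages))
        ]
    )


class TestHaplotypeDiversity:
    def test_identical_sequences_give_zero(self):
        assert haplotype_diversity(aln_of(["ACGT"] * 5)) == 0.0

    def test_all_distinct_gives_maximal(self):
        a = aln_of(["AAAA", "AAAC", "AACC", "ACCC"])
        assert haplotype_diversity(a) == pytest.approx((4 / 3) * (1 - 4 / 16))

    def test_partial_sharing(self):
        # haplotype counts {2,1,1}: H = (4/3)(1 - (0.25 + 0.0625 + 0.0625))
        a = aln_of(["AAAA", "AAAA", "AACC", "ACCC"])
        assert haplotype_diversity(a) == pytest.approx(0.8333, abs=1e-4)

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            haplotype_diversity(aln_of(["ACGT"]))

    def test_n_matching_sequences_cluster_together(self):
        # with pairwise N-deletion, "ANGT" matches "ACGT"
        a = aln_of(["ACGT", "ANGT", "TTTT"])
        assert haplotype_diversity(a) == pytest.approx((3 / 2) * (1 - (4 + 1) / 9))


class TestPairwiseDifferences:
    def test_single_difference(self):
        s1 = "A" * 741
        s2 = "A" * 740 + "C"
        a = aln_of([s1, s2])
        assert mean_pairwise_differences(a) == 1.0
        assert nucleotide_diversity(a) == pytest.approx(1 / 741)

    def test_identical_sequences(self):
        assert mean_pairwise_differences(aln_of(["ACGT"] * 3)) == 0.0

    def test_mean_over_three_pairs(self):
        # pairwise differences {2, 4, 6} -> mean 4
        s1 = "AAAAAAAA"
        s2 = "CCAAAAAA"  # 2 vs s1
        s3 = "CCCCCCAA"  # 6 vs s1, 4 vs s2
        assert mean_pairwise_differences(aln_of([s1, s2, s3])) == pytest.approx(4.0)

    def test_pairwise_n_deletion_rescales(self):
        # 1 difference over 3 comparable sites, rescaled to L=4
        a = aln_of(["ACGT", "NCGA"])
        assert mean_pairwise_differences(a) == pytest.approx(4 / 3)


class TestTajimasD:
    def test_undefined_for_no_variation(self):
        assert np.isnan(tajimas_d(aln_of(["ACGT"] * 5)))

    def test_sign_follows_pi_minus_watterson(self):
        rngs = np.random.default_rng(4)
        for _ in range(10):
            mat = rngs.integers(0, 4, size=(8, 60)).astype(np.uint8)
            from paleoabc.data import HeterochronousAlignment

            a = HeterochronousAlignment.from_matrix(
                mat, [f"s{i}" for i in range(8)], [0.0] * 8, ["d"] * 8
            )
            S = segregating_sites(a)
            if S == 0:
                continue
            a1 = sum(1 / i for i in range(1, 8))
            expected_sign = np.sign(mean_pairwise_differences(a) - S / a1)
            assert np.sign(tajimas_d(a)) == expected_sign

    def test_neutral_constant_size_mean_near_zero(self, rng):
        from paleoabc.coalsim import SampleDesign, simulate_genealogy
        from paleoabc.demography import Demography, Epoch
        from paleoabc.mutation import MutationModel, apply_mutations

        demog = Demography(demes={"d": [Epoch(0.0, 1000.0)]})
        design = SampleDesign.from_counts([("d", 0.0, 10)])
        model = MutationModel(mu=2e-6, L=741, alpha=1e9, ts_bias=0.5)
        vals = []
        for _ in range(2000):
            g = simulate_genealogy(demog, design, rng)
            d = tajimas_d(apply_mutations(g, model, rng))
            if not np.isnan(d):
                vals.append(d)
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        # Tajima's D is approximately mean-zero under neutrality; the known
        # small-sample skew motivates the extra absolute slack
        assert abs(vals.mean()) < 3 * se + 0.1


class TestFst:
    def test_same_group_twice_gives_zero(self):
        g = aln_of(["ACGT", "ACGA"])
        assert pairwise_fst(g, g) == 0.0

    def test_fixed_difference_gives_one(self):
        a = aln_of(["AAAA", "AAAA"])
        b = aln_of(["TTTT", "TTTT"])
        assert pairwise_fst(a, b) == 1.0

    def test_no_between_variation_is_undefined(self):
        a = aln_of(["AAAA", "AAAA"])
        assert np.isnan(pairwise_fst(a, a))


class TestStatVector:
    def test_three_groups_give_31_entries(self, tiny_alignment):
        sv = compute_stat_vector(tiny_alignment)
        assert len(sv) == 3 * 7 + 3 + 7

    def test_permutation_invariance(self, tiny_alignment):
        sv = compute_stat_vector(tiny_alignment)
        perm = [1, 0, 3, 2, 5, 4]  # swap samples within each deme
        sv2 = compute_stat_vector(tiny_alignment.subset(perm))
        np.testing.assert_allclose(sv.values, sv2.values)
        np.testing.assert_array_equal(sv.mask, sv2.mask)

    def test_io_consistency(self, tiny_alignment, tmp_path):
        from paleoabc.data import read_dataset, write_dataset

        fa, tsv = tmp_path / "a.fasta", tmp_path / "a.tsv"
        write_dataset(tiny_alignment, fa, tsv)
        sv_mem = compute_stat_vector(tiny_alignment)
        sv_disk = compute_stat_vector(read_dataset(fa, tsv))
        np.testing.assert_allclose(sv_mem.values, sv_disk.values)

    def test_masked_entries_encoded_as_zero(self):
        a = aln_of(["ACGT"] * 4, demes=["x", "x", "y", "y"])
        sv = compute_stat_vector(a)
        # no variation anywhere: Tajima's D and FST are masked, encoded 0
        assert sv["fst_x_y"] == 0.0
        assert sv.mask[list(sv.names).index("fst_x_y")]
        assert sv["pooled_tajd"] == 0.0

    def test_export_one_row_tsv(self, tiny_alignment, tmp_path):
        import pandas as pd

        sv = compute_stat_vector(tiny_alignment)
        path = tmp_path / "sv.tsv"
        sv.to_tsv(path)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == list(sv.names)
        np.testing.assert_allclose(df.iloc[0].to_numpy(), sv.values)


def test_watterson_and_pi_estimators_agree_in_expectation(rng):
    """On neutral constant-size data, S/a1 and Pi estimate the same theta."""
    from paleoabc.coalsim import SampleDesign, simulate_genealogy
    from paleoabc.demography import Demography, Epoch
    from paleoabc.mutation import MutationModel, apply_mutations

    N, n, mu, L = 800.0, 12, 2e-6, 741
    demog = Demography(demes={"d": [Epoch(0.0, N)]})
    design = SampleDesign.from_counts([("d", 0.0, n)])
    model = MutationModel(mu=mu, L=L, alpha=1e9, ts_bias=0.5)
    a1 = sum(1 / i for i in range(1, n))
    watt, pis = [], []
    for _ in range(1500):
        aln = apply_mutations(simulate_genealogy(demog, design, rng), model, rng)
        watt.append(segregating_sites(aln) / a1)
        pis.append(mean_pairwise_differences(aln))
    diff = np.array(watt) - np.array(pis)
    se = diff.std(ddof=1) / np.sqrt(len(diff))
    assert abs(diff.mean()) < 3 * se + 0.02 * np.mean(watt)
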