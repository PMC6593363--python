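"""HWE and parity tests, Spearman/ward.D2 clustering, set summaries."""

import numpy as np
import pandas as pd
import pytest

from cnvrpipe import popgen_stats as ps
from cnvrpipe.core_io import CN_UNKNOWN, GenomeLayout

from conftest import make_call, make_cnvr


class TestHwe:
    def test_exact_hwe_proportions_give_chi2_zero(self):
        res = ps.hwe_test({0: 25, 1: 50, 2: 25})
        assert res.qualifies and res.mapping == "DEL-side"
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.in_hwe

    def test_textbook_goodness_of_fit_case(self):
        # independent oracle (hand-computed Pearson chi2, verified in R):
        # obs (1, 10, 89), q = 0.06, expected (0.36, 11.28, 88.36)
        # chi2 = 1.287662, p = 0.256479
        res = ps.hwe_test({0: 1, 1: 10, 2: 89})
        assert res.chi2 == pytest.approx(1.287662, abs=1e-6)
        assert res.p_value == pytest.approx(0.256479, abs=1e-6)
        assert res.in_hwe

    def test_no_heterozygotes_strongly_rejected(self):
        # obs (50, 0, 50): q=0.5, expected (25, 50, 25), chi2 = 100 exactly
        res = ps.hwe_test({0: 50, 2: 50})
        assert res.chi2 == pytest.approx(100.0)
        assert res.p_value < 1e-20
        assert not res.in_hwe

    def test_dup_side_mapping(self):
        res = ps.hwe_test({2: 25, 3: 50, 4: 25})
        assert res.qualifies and res.mapping == "DUP-side"
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_multi_allelic_spectrum_not_testable(self):
        res = ps.hwe_test({0: 10, 3: 10, 2: 80})
        assert not res.qualifies and res.reason == "multi-allelic"
        assert res.chi2 is None and res.p_value is None

    def test_monomorphic_not_testable(self):
        res = ps.hwe_test({2: 100})
        assert not res.qualifies and res.reason == "monomorphic"

    def test_cn_unknown_must_be_excluded(self):
        with pytest.raises(ValueError):
            ps.hwe_test({0: 5, 2: 5, CN_UNKNOWN: 3})

    def test_agrees_with_multinomial_enumeration_small_n(self):
        # brute-force re-derivation of the statistic on all triples n<=20
        from scipy.stats import chi2 as chi2_dist

        for n_aa in range(0, 8):
            for n_het in range(0, 8):
                for n_AA in range(0, 8):
                    n = n_aa + n_het + n_AA
                    if n == 0:
                        continue
                    present = sum(1 for c in (n_aa, n_het, n_AA) if c > 0)
                    res = ps.hwe_test({0: n_aa, 1: n_het, 2: n_AA})
                    if present < 2:
                        assert not res.qualifies
                        continue
                    q = (2 * n_aa + n_het) / (2 * n)
                    p = 1 - q
                    exp = [n * q * q, 2 * n * p * q, n * p * p]
                    stat = sum(
                        (o - e) ** 2 / e
                        for o, e in zip((n_aa, n_het, n_AA), exp)
                        if e > 0
                    )
                    assert res.chi2 == pytest.approx(stat, rel=1e-12)
                    assert res.p_value == pytest.approx(
                        float(chi2_dist.sf(stat, 1)), rel=1e-12
                    )


class TestParity:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({0: 5, 1: 20, 2: 75}, True),    # even 80 >= odd 20
            ({1: 60, 2: 40}, False),         # 40 < 60
            ({1: 50, 2: 50}, True),          # tie passes
            ({6: 10, 5: 5}, True),           # CN6 counts as even
        ],
    )
    def test_even_vs_odd_rule(self, counts, expected):
        assert ps.parity_test(counts) is expected

    def test_zero_samples_not_evaluated(self):
        assert ps.parity_test({}) is None


class TestClustering:
    def test_identical_vectors_merge_first_at_zero(self):
        gm = pd.DataFrame(
            {"a": [0, 1, 3, 4, 0, 2], "b": [0, 1, 3, 4, 0, 2],
             "c": [4, 3, 1, 0, 2, 0], "d": [4, 3, 1, 0, 2, 1]},
            index=[f"r{i}" for i in range(6)],
        )
        Z, labels, _ = ps.cluster_samples(gm)
        assert labels == ["a", "b", "c", "d"]
        # first merge joins a and b at height ~0
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-9)

    def test_ward_d2_reproduces_hand_worked_merge_order(self):
        # 4-point dissimilarity d(A,B)=1, d(C,D)=2, cross=10;
        # ward.D2 heights verified independently in R hclust:
        # merges (A,B)@1, (C,D)@2, (AB,CD)@14.05347
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        D = np.array(
            [[0, 1, 10, 10], [1, 0, 10, 10], [10, 10, 0, 2], [10, 10, 2, 0]],
            dtype=float,
        )
        Z = linkage(squareform(D), method="ward")
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == pytest.approx(1.0)
        assert {int(Z[1, 0]), int(Z[1, 1])} == {2, 3}
        assert Z[1, 2] == pytest.approx(2.0)
        assert Z[2, 2] == pytest.approx(14.05347, abs=1e-5)

    def test_constant_vector_gets_max_distance_with_warning(self):
        gm = pd.DataFrame(
            {"a": [2, 2, 2, 2], "b": [0, 1, 3, 4], "c": [0, 1, 3, 3]},
            index=[f"r{i}" for i in range(4)],
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            dist = ps.spearman_distance_matrix(gm)
        assert dist.loc["a", "b"] == 2.0

    def test_missing_genotypes_pairwise_excluded(self):
        gm = pd.DataFrame(
            {"a": [0, 1, 3, CN_UNKNOWN], "b": [0, 1, 3, 4]},
            index=[f"r{i}" for i in range(4)],
        )
        dist = ps.spearman_distance_matrix(gm)
        # over shared CNVRs r0..r2 the vectors are identical
        assert dist.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_newick_serialisation_contains_all_leaves(self):
        gm = pd.DataFrame(
            np.array([[0, 1, 3, 4], [0, 1, 3, 3], [4, 3, 1, 0]]).T,
            columns=["x", "y", "z"], index=[f"r{i}" for i in range(4)],
        )
        Z, labels, _ = ps.cluster_samples(gm)
        nwk = ps.linkage_to_newick(Z, labels)
        assert nwk.endswith(";")
        for leaf in labels:
            assert leaf in nwk


class TestOverlapFraction:
    def test_subset_is_fully_covered(self):
        a = [make_cnvr([make_call(1001, 5000, 1)])]
        b = [make_cnvr([make_call(1001, 5000, 1)]),
             make_cnvr([make_call(9001, 12000, 1)])]
        assert ps.overlap_fraction(a, b) == 1.0

    def test_disjoint_sets_are_zero(self):
        a = [make_cnvr([make_call(1001, 5000, 1)])]
        b = [make_cnvr([make_call(9001, 12000, 1)])]
        assert ps.overlap_fraction(a, b) == 0.0

    def test_single_shared_base_counts(self):
        a = [make_cnvr([make_call(1, 10, 1)])]
        b = [make_cnvr([make_call(10, 20, 1)])]
        assert ps.overlap_fraction(a, b) == 1.0

    def test_empty_a_not_applicable(self):
        assert ps.overlap_fraction([], [make_cnvr([make_call(1, 10, 1)])]) is None

    def test_asymmetry(self):
        a = [make_cnvr([make_call(1001, 5000, 1)])]
        b = [make_cnvr([make_call(4001, 8000, 1)]),
             make_cnvr([make_call(90001, 95000, 1)])]
        assert ps.overlap_fraction(a, b) == 1.0
        assert ps.overlap_fraction(b, a) == 0.5


class TestBreedSpecific:
    def gm_and_meta(self, genotypes):
        gm = pd.DataFrame(genotypes, index=["r1"])
        meta = pd.DataFrame(
            {
                "sample_id": list(genotypes),
                "breed": ["HER", "HER", "HER", "SIM"],
                "dataset_id": "A",
                "coverage": 10.0,
            }
        )
        return gm, meta

    def test_three_her_carriers_is_her_specific(self):
        gm, meta = self.gm_and_meta({"h1": [1], "h2": [1], "h3": [0], "s1": [2]})
        assert ps.breed_specific(gm, meta)["HER"] == ["r1"]

    def test_cross_breed_carrier_disqualifies(self):
        gm, meta = self.gm_and_meta({"h1": [1], "h2": [1], "h3": [2], "s1": [1]})
        out = ps.breed_specific(gm, meta)
        assert out["HER"] == [] and out["SIM"] == []

    def test_single_carrier_not_enough(self):
        gm, meta = self.gm_and_meta({"h1": [1], "h2": [2], "h3": [2], "s1": [2]})
        assert ps.breed_specific(gm, meta)["HER"] == []


class TestDensity:
    def test_counts_per_mb(self):
        layout = GenomeLayout(("c1", "c2"), (10_000_000, 5_000_000))
        cnvrs = [
            make_cnvr([make_call(i * 100_000 + 1, i * 100_000 + 5000, 1, chrom="c1")])
            for i in range(10)
        ]
        for r in cnvrs:
            r.category = "DEL"
        df = ps.density_by_chromosome(cnvrs, layout).set_index("chrom")
        assert df.loc["c1", "n_cnvrs"] == 10
        assert df.loc["c1", "per_mb"] == pytest.approx(1.0)
        assert df.loc["c2", "n_cnvrs"] == 0 and df.loc["c2", "per_mb"] == 0.0

    def test_category_split_sums_to_total(self):
        layout = GenomeLayout(("c1",), (1_000_000,))
        cats = ["DEL", "AMP", "MIX", "DEL"]
        cnvrs = []
        for i, cat in enumerate(cats):
            r = make_cnvr([make_call(i * 50_000 + 1, i * 50_000 + 5000, 1, chrom="c1")])
            r.category = cat
            cnvrs.append(r)
        df = ps.density_by_chromosome(cnvrs, layout)
        row = df.iloc[0]
        assert row["DEL"] + row["AMP"] + row["MIX"] == row["n_cnvrs"]

    def test_unknown_chromosome_is_named_in_error(self):
        layout = GenomeLayout(("c1",), (1_000_000,))
        r = make_cnvr([make_call(1, 5000, 1, chrom="cX")])
        with pytest.raises(ValueError, match="cX"):
            ps.density_by_chromosome([r], layout)


def test_hwe_type_one_error_under_exact_hwe():
    """Genotypes sampled under HWE are almost never flagged at alpha=1e-5."""
    rng = np.random.default_rng(123)
    q, n, reps = 0.3, 500, 2000
    geno = rng.binomial(2, q, size=(reps, n))  # allele dosage per sample
    rejections = 0
    for row in geno:
        counts = {0: int((row == 2).sum()), 1: int((row == 1).sum()),
                  2: int((row == 0).sum())}
        res = ps.hwe_test(counts)
        if res.qualifies and not res.in_hwe:
            rejections += 1
    # expected rate <= 0.1%; allow 3x binomial SE above it
    limit = 0.001 * reps + 3 * np.sqrt(reps * 0.001 * 0.999)
    assert rejections <= limit
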