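"""CNVR construction rules: reciprocal overlap, clustering, genotypes."""

import numpy as np
import pytest

from cnvrpipe import cnvr_builder as cb
from cnvrpipe.core_io import CN_UNKNOWN, GenomeLayout

from conftest import make_call, make_cnvr


def brute_force_components(calls, ro=0.5):
    """Independent oracle: explicit all-pairs edge list + DFS."""
    n = len(calls)
    adj = {i: [] for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if cb.ro_satisfied(calls[i], calls[j], ro):
                adj[i].append(j)
                adj[j].append(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k])
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


class TestReciprocalOverlap:
    def test_exact_50_percent_boundary_satisfies(self):
        fa, fb = cb.reciprocal_overlap((1001, 5000), (3001, 7000))
        assert (fa, fb) == (0.5, 0.5)
        assert cb.ro_satisfied(make_call(1001, 5000, 1), make_call(3001, 7000, 1, "S2"))

    def test_asymmetric_overlap_fails(self):
        fa, fb = cb.reciprocal_overlap((1001, 5000), (4001, 12000))
        assert (fa, fb) == (0.25, 0.125)
        assert not cb.ro_satisfied(
            make_call(1001, 5000, 1), make_call(4001, 12000, 1, "S2")
        )

    def test_identity_is_full_overlap(self):
        assert cb.reciprocal_overlap((1001, 5000), (1001, 5000)) == (1.0, 1.0)

    def test_different_chromosomes_never_satisfy(self):
        a = make_call(1001, 5000, 1, chrom="chr1")
        b = make_call(1001, 5000, 1, sample="S2", chrom="chr2")
        assert not cb.ro_satisfied(a, b)


class TestClusterCnvs:
    def test_boundary_pair_is_one_cnvr(self):
        calls = [make_call(1001, 5000, 1), make_call(3001, 7000, 1, sample="S2")]
        (r,) = cb.cluster_cnvs(calls)
        assert (r.start, r.end) == (1001, 7000)
        assert len(r.members) == 2

    def test_single_linkage_chains_through_middle(self):
        # A~B and B~C but not A~C -> one CNVR by transitive closure
        a = make_call(1001, 9000, 1, sample="S1")
        b = make_call(5001, 13000, 1, sample="S2")
        c = make_call(9001, 17000, 1, sample="S3")
        assert cb.ro_satisfied(a, b) and cb.ro_satisfied(b, c)
        assert not cb.ro_satisfied(a, c)
        (r,) = cb.cluster_cnvs([a, b, c])
        assert (r.start, r.end) == (1001, 17000)

    def test_different_chromosomes_stay_apart(self):
        calls = [
            make_call(1001, 5000, 1, chrom="chr1"),
            make_call(1001, 5000, 1, sample="S2", chrom="chr2"),
        ]
        assert len(cb.cluster_cnvs(calls)) == 2

    def test_partition_property_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(2, 50))
            calls = []
            for i in range(n):
                start = int(rng.integers(1, 100)) * 1000 + 1
                width = int(rng.integers(3, 15)) * 1000
                cn = int(rng.choice([0, 1, 3, 4]))
                calls.append(make_call(start, start + width - 1, cn, sample=f"S{i}"))
            cnvrs = cb.cluster_cnvs(calls)
            # every call in exactly one CNVR
            assert sum(len(r.members) for r in cnvrs) == n
            got = {
                frozenset(calls.index(m) for m in r.members) for r in cnvrs
            }
            assert got == brute_force_components(calls)


class TestCategorize:
    @pytest.mark.parametrize(
        "cns,expected",
        [([0, 1], "DEL"), ([3, 8], "AMP"), ([1, 3], "MIX"), ([0], "DEL"),
         ([4, 5, 6], "AMP"), ([0, 1, 8], "MIX")],
    )
    def test_category_from_member_genotypes(self, cns, expected):
        members = [
            make_call(1001, 5000, cn, sample=f"S{i}") for i, cn in enumerate(cns)
        ]
        assert cb.categorize(make_cnvr(members)) == expected

    def test_empty_members_is_error(self):
        r = make_cnvr([make_call(1001, 5000, 1)])
        r.members = []
        with pytest.raises(ValueError):
            cb.categorize(r)


class TestFilterSingletons:
    def test_two_cnvs_same_sample_is_singleton(self):
        r = make_cnvr([make_call(1001, 5000, 1), make_call(1001, 4000, 0)])
        kept, n = cb.filter_singletons([r])
        assert kept == [] and n == 1

    def test_two_distinct_samples_kept(self):
        r = make_cnvr([make_call(1001, 5000, 1), make_call(1001, 5000, 0, sample="S2")])
        kept, n = cb.filter_singletons([r])
        assert kept == [r] and n == 0

    def test_min_samples_1_removes_nothing(self):
        r = make_cnvr([make_call(1001, 5000, 1)])
        assert cb.filter_singletons([r], min_samples=1) == ([r], 0)


class TestAssignGenotypes:
    def test_largest_aggregate_width_wins(self):
        r = make_cnvr([
            make_call(1001, 4000, 1),  # CN1, 3 kb
            make_call(1001, 6000, 3),  # CN3, 5 kb -> larger aggregate width
        ])
        assert cb.assign_genotypes(r, ["S1"])["S1"] == 3

    def test_tie_resolves_toward_cn2(self):
        r = make_cnvr([
            make_call(1001, 5000, 0),  # CN0, 4 kb, |0-2|=2
            make_call(1001, 5000, 3),  # CN3, 4 kb, |3-2|=1 -> closer to CN2
        ])
        assert cb.assign_genotypes(r, ["S1"])["S1"] == 3

    def test_aggregation_across_discrete_cnvs(self):
        r = make_cnvr([
            make_call(1001, 3000, 1),   # CN1, 2 kb
            make_call(5001, 8000, 1),   # CN1, 3 kb -> aggregate 5 kb
            make_call(1001, 5000, 0),   # CN0, 4 kb
        ])
        assert cb.assign_genotypes(r, ["S1"])["S1"] == 1

    def test_residual_tie_takes_lower_cn(self):
        r = make_cnvr([
            make_call(1001, 5000, 1),
            make_call(1001, 5000, 3),
        ])
        assert cb.assign_genotypes(r, ["S1"])["S1"] == 1

    def test_non_member_sample_is_provisional_cn2(self):
        r = make_cnvr([make_call(1001, 5000, 1)])
        assert cb.assign_genotypes(r, ["S1", "S9"])["S9"] == 2

    def test_permutation_invariant_in_member_order(self):
        members = [
            make_call(1001, 3000, 1),
            make_call(5001, 8000, 1),
            make_call(1001, 5000, 0),
        ]
        r1 = make_cnvr(members)
        r2 = make_cnvr(members[::-1])
        assert cb.assign_genotypes(r1, ["S1"]) == cb.assign_genotypes(r2, ["S1"])


class TestCn2Correction:
    def build(self, spans_members, all_samples):
        cnvrs = []
        for i, members in enumerate(spans_members):
            r = make_cnvr(members, cnvr_id=f"r{i}")
            r.genotypes = cb.assign_genotypes(r, all_samples)
            cnvrs.append(r)
        return cnvrs

    def test_non_overlapping_cnvrs_produce_no_unknowns(self):
        cnvrs = self.build(
            [
                [make_call(1001, 6000, 1, sample="S1"),
                 make_call(1001, 6000, 0, sample="S2")],
                [make_call(50001, 56000, 3, sample="S2"),
                 make_call(50001, 56000, 3, sample="S3")],
            ],
            ["S1", "S2", "S3"],
        )
        cb.cn2_correction(cnvrs)
        assert all(CN_UNKNOWN not in r.genotypes.values() for r in cnvrs)

    def test_sample_with_cnv_in_overlapping_cnvr_becomes_unknown(self):
        cnvrs = self.build(
            [
                [make_call(1001, 6000, 1, sample="S1"),
                 make_call(1001, 6000, 1, sample="S2")],
                [make_call(4001, 9000, 3, sample="S3"),
                 make_call(4001, 9000, 3, sample="S4")],
            ],
            ["S1", "S2", "S3", "S4"],
        )
        cb.cn2_correction(cnvrs)
        r0, r1 = cnvrs
        assert r0.genotypes["S3"] == CN_UNKNOWN and r0.genotypes["S4"] == CN_UNKNOWN
        assert r1.genotypes["S1"] == CN_UNKNOWN and r1.genotypes["S2"] == CN_UNKNOWN

    def test_member_of_both_cnvrs_keeps_genotypes(self):
        cnvrs = self.build(
            [
                [make_call(1001, 6000, 1, sample="S1"),
                 make_call(1001, 6000, 1, sample="S2")],
                [make_call(4001, 9000, 3, sample="S1"),
                 make_call(4001, 9000, 3, sample="S4")],
            ],
            ["S1", "S2", "S4"],
        )
        cb.cn2_correction(cnvrs)
        r0, r1 = cnvrs
        assert r0.genotypes["S1"] == 1 and r1.genotypes["S1"] == 3

    def test_correction_is_idempotent(self):
        cnvrs = self.build(
            [
                [make_call(1001, 6000, 1, sample="S1"),
                 make_call(1001, 6000, 1, sample="S2")],
                [make_call(4001, 9000, 3, sample="S3"),
                 make_call(4001, 9000, 3, sample="S4")],
            ],
            ["S1", "S2", "S3", "S4"],
        )
        cb.cn2_correction(cnvrs)
        snapshot = [dict(r.genotypes) for r in cnvrs]
        cb.cn2_correction(cnvrs)
        assert [dict(r.genotypes) for r in cnvrs] == snapshot


class TestMergeCnvrSets:
    def test_bookended_regions_coalesce(self):
        sets = [[make_cnvr([make_call(1001, 2000, 1)])],
                [make_cnvr([make_call(2001, 3000, 1)])]]
        df, summary = cb.merge_cnvr_sets(sets, mode="union")
        assert len(df) == 1
        assert (df.iloc[0]["start"], df.iloc[0]["end"]) == (1001, 3000)

    def test_unique_coords_counts_identical_once(self):
        r = [make_call(1001, 5000, 1)]
        sets = [[make_cnvr(r)], [make_cnvr(r)]]
        df, summary = cb.merge_cnvr_sets(sets, mode="unique_coords")
        assert summary.n_regions == 1

    def test_genome_percentage_arithmetic(self):
        layout = GenomeLayout(("c",), (100_000,))
        sets = [[
            make_cnvr([make_call(1001, 3000, 1)]),
            make_cnvr([make_call(50001, 53000, 1)]),
        ]]
        df, summary = cb.merge_cnvr_sets(sets, mode="union", layout=layout)
        assert summary.total_bp == 5000
        assert summary.pct_genome == pytest.approx(5.0)


def test_category_counts_sum_to_total():
    rng = np.random.default_rng(7)
    calls = []
    for i in range(60):
        start = int(rng.integers(1, 200)) * 1000 + 1
        width = int(rng.integers(3, 10)) * 1000
        cn = int(rng.choice([0, 1, 3, 4]))
        calls.append(make_call(start, start + width - 1, cn, sample=f"S{i % 7}"))
    cnvrs = cb.cluster_cnvs(calls)
    for r in cnvrs:
        r.category = cb.categorize(r)
    counts = {cat: sum(1 for r in cnvrs if r.category == cat)
              for cat in ("DEL", "AMP", "MIX")}
    assert sum(counts.values()) == len(cnvrs)
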