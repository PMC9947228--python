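"""Hypergeometric relation detection, distinctness, clinical comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import biclink as b
from biclink.errors import DomainError
from biclink.nmf import Bicluster, BiclusterSet
from biclink.relations import Relation


def hypergeom_enumeration_oracle(N, K, n, k):
    """Upper tail by exact pmf summation with integer combinatorics."""
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return acc / total


def make_set(domain, members_by_id, features_by_id=None):
    features_by_id = features_by_id or {}
    bcs = [
        Bicluster(
            id=i,
            domain=domain,
            participants=frozenset(m),
            features=frozenset(features_by_id.get(i, {f"f_{i}"})),
            mean_loading=1.0,
        )
        for i, m in members_by_id.items()
    ]
    return BiclusterSet(domain, bcs)


class TestHypergeomOverlap:
    def test_zero_overlap_is_one(self):
        assert b.hypergeom_overlap_p(100, 30, 20, 0) == 1.0

    def test_full_overlap_10_5_5(self):
        assert b.hypergeom_overlap_p(10, 5, 5, 5) == pytest.approx(1 / 252, rel=1e-12)

    def test_matches_enumeration_sweep(self):
        """All configurations with N <= 30 agree with pmf summation."""
        for N in range(1, 31):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        got = b.hypergeom_overlap_p(N, K, n, k)
                        want = hypergeom_enumeration_oracle(N, K, n, k)
                        assert abs(got - want) <= 1e-12 + 1e-9 * want

    def test_large_configuration_oracle(self):
        for k in range(41):
            got = b.hypergeom_overlap_p(1000, 50, 40, k)
            want = hypergeom_enumeration_oracle(1000, 50, 40, k)
            assert got == pytest.approx(want, abs=1e-12, rel=1e-9)

    def test_monotone_in_k(self):
        ps = [b.hypergeom_overlap_p(500, 60, 40, k) for k in range(41)]
        assert (np.diff(ps) <= 1e-15).all()

    def test_symmetry_in_group_sizes(self, rng):
        for _ in range(1000):
            N = int(rng.integers(2, 200))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert b.hypergeom_overlap_p(N, K, n, k) == pytest.approx(
                b.hypergeom_overlap_p(N, n, K, k), rel=1e-9
            )

    def test_inconsistent_counts(self):
        with pytest.raises(DomainError):
            b.hypergeom_overlap_p(10, 11, 5, 2)
        with pytest.raises(DomainError):
            b.hypergeom_overlap_p(10, 5, 5, 6)


class TestFindRelations:
    def test_candidate_arithmetic(self):
        g = make_set("genotype", {f"G{i}": {f"p{i}"} for i in range(153)})
        l = make_set("lipidome", {f"P{i}": {f"q{i}"} for i in range(71)})
        rs = b.find_relations(g, l, N=1000, alpha=1e-30)
        assert rs.counts["candidates"] == 10_863

    def test_identical_sets_detected(self):
        members = {f"p{i}" for i in range(30)}
        g = make_set("genotype", {"G1": members})
        l = make_set("lipidome", {"P1": members})
        rs = b.find_relations(g, l, N=1000, alpha=0.01)
        assert len(rs.relations) == 1
        r = rs.relations[0]
        assert r.k == 30
        assert r.p_hypergeom <= hypergeom_enumeration_oracle(1000, 30, 30, 30) * (1 + 1e-9)
        assert r.p_hypergeom < 1e-20

    def test_disjoint_sets_not_retained(self):
        g = make_set("genotype", {"G1": {"p1", "p2"}})
        l = make_set("lipidome", {"P1": {"p3", "p4"}})
        rs = b.find_relations(g, l, N=100, alpha=0.01)
        assert len(rs.relations) == 0
        assert rs.counts["candidates"] == 1

    def test_ids_assigned_by_ascending_p(self):
        base = {f"p{i}" for i in range(50)}
        g = make_set("genotype", {"G1": base, "G2": set(list(base)[:20]) | {"x1", "x2"}})
        l = make_set("lipidome", {"P1": base})
        rs = b.find_relations(g, l, N=500, alpha=0.05)
        ps = [r.p_hypergeom for r in rs.relations]
        assert ps == sorted(ps)
        assert [r.id for r in rs.relations] == [f"R{i+1}" for i in range(len(ps))]


class TestDistinctness:
    def rel(self, rid, gid, parts, snps):
        return Relation(
            id=rid, genotype_bicluster_id=gid, lipidome_bicluster_id="P",
            shared_participants=frozenset(), k=0, p_hypergeom=1e-5,
            genotype_participants=frozenset(parts), genotype_snps=frozenset(snps),
        )

    def wrap(self, rels):
        return b.RelationSet(rels, cohort_size=100, alpha=0.01,
                             counts={"candidates": 10, "significant": len(rels)})

    def test_single_relation_fully_unique(self):
        rs = b.score_distinctness(self.wrap([self.rel("R1", "G1", {"a"}, {"s1"})]))
        r = rs.relations[0]
        assert r.unique_snp_fraction == 1.0 and r.unique_participant_fraction == 1.0
        assert r.distinct

    def test_shared_bicluster_zero_uniqueness(self):
        r1 = self.rel("R1", "G1", {"a", "b"}, {"s1", "s2"})
        r2 = self.rel("R2", "G1", {"a", "b"}, {"s1", "s2"})
        rs = b.score_distinctness(self.wrap([r1, r2]))
        for r in rs.relations:
            assert r.unique_snp_fraction == 0.0
            assert r.unique_participant_fraction == 0.0
            assert not r.distinct

    def test_three_relation_set_arithmetic(self):
        r1 = self.rel("R1", "G1", {"a", "b", "c", "d"}, {"s1", "s2", "s3", "s4"})
        r2 = self.rel("R2", "G2", {"c", "e"}, {"s4", "s5"})
        r3 = self.rel("R3", "G3", {"f"}, {"s6"})
        rs = b.score_distinctness(self.wrap([r1, r2, r3]))
        by_id = {r.id: r for r in rs.relations}
        assert by_id["R1"].unique_snp_fraction == pytest.approx(3 / 4)
        assert by_id["R1"].unique_participant_fraction == pytest.approx(3 / 4)
        assert by_id["R2"].unique_snp_fraction == pytest.approx(1 / 2)
        assert not by_id["R2"].distinct  # needs strictly more than half
        assert by_id["R3"].distinct
        assert rs.counts["distinct"] == 2


class TestMultifinality:
    def make_rs(self, pairs):
        rels = [
            Relation(id=f"R{i}", genotype_bicluster_id=g, lipidome_bicluster_id=l,
                     shared_participants=frozenset(), k=0, p_hypergeom=1e-4)
            for i, (g, l) in enumerate(pairs)
        ]
        return b.RelationSet(rels, 100, 0.01)

    @pytest.mark.parametrize(
        "pairs,expected",
        [
            ([("G1", "L1"), ("G1", "L2")], (1, 0)),
            ([("G1", "L1"), ("G2", "L1")], (0, 1)),
            ([("G1", "L1"), ("G1", "L2"), ("G2", "L2"), ("G3", "L3")], (1, 1)),
        ],
    )
    def test_definitions(self, pairs, expected):
        assert b.summarize_multifinality(self.make_rs(pairs)) == expected

    def test_random_sets_match_counting_oracle(self, rng):
        for _ in range(20):
            pairs = [
                (f"G{rng.integers(5)}", f"L{rng.integers(5)}") for _ in range(rng.integers(1, 15))
            ]
            pairs = list(dict.fromkeys(pairs))
            got = b.summarize_multifinality(self.make_rs(pairs))
            gs = [p[0] for p in pairs]
            ls = [p[1] for p in pairs]
            want = (
                sum(1 for g in set(gs) if gs.count(g) >= 2),
                sum(1 for l in set(ls) if ls.count(l) >= 2),
            )
            assert got == want


class TestCompareClinical:
    def make_relation(self, members):
        return Relation(
            id="R1", genotype_bicluster_id="G1", lipidome_bicluster_id="P1",
            shared_participants=frozenset(), k=0, p_hypergeom=1e-4,
            genotype_participants=frozenset(members),
        )

    def test_welch_closed_form_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.5, 2.2, 3.3])
        y = np.array([2.0, 2.5, 4.0, 5.0, 6.0, 3.5, 4.2, 5.1])
        idx = [f"m{i}" for i in range(6)] + [f"r{i}" for i in range(8)]
        clinical = pd.DataFrame({"v": np.concatenate([x, y])}, index=idx)
        comp = b.compare_clinical(self.make_relation(idx[:6]), clinical)
        row = comp.results.iloc[0]
        sx, sy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t = (x.mean() - y.mean()) / np.sqrt(sx + sy)
        df = (sx + sy) ** 2 / (sx**2 / (len(x) - 1) + sy**2 / (len(y) - 1))
        p = 2 * stats.t.sf(abs(t), df)
        assert row["t"] == pytest.approx(t, abs=1e-10)
        assert row["p"] == pytest.approx(p, abs=1e-10)

    def test_shifted_variable_detected(self, rng):
        members = [f"m{i}" for i in range(50)]
        rest = [f"r{i}" for i in range(50)]
        vals = np.concatenate([rng.normal(3.0, 1.0, 50), rng.normal(0.0, 1.0, 50)])
        clinical = pd.DataFrame({"v": vals}, index=members + rest)
        comp = b.compare_clinical(self.make_relation(members), clinical)
        assert comp.results.iloc[0]["p"] < 1e-6

    def test_null_calibration_small(self, rng):
        """Null member assignments give Uniform(0,1) Welch p-values."""
        n = 120
        idx = [f"p{i}" for i in range(n)]
        ps = []
        for _ in range(400):
            clinical = pd.DataFrame({"v": rng.normal(size=n)}, index=idx)
            members = list(rng.choice(idx, 30, replace=False))
            comp = b.compare_clinical(self.make_relation(members), clinical)
            ps.append(comp.results.iloc[0]["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_reported_nan(self):
        idx = [f"p{i}" for i in range(10)]
        clinical = pd.DataFrame(
            {"flat": np.ones(10), "ok": np.arange(10.0)}, index=idx
        )
        comp = b.compare_clinical(self.make_relation(idx[:4]), clinical)
        res = comp.results.set_index("variable")
        assert np.isnan(res.loc["flat", "p"])
        assert np.isfinite(res.loc["ok", "p"])
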