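import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitocomp.distances import (
    DistanceMatrix,
    delimit,
    distance_matrix,
    global_align,
    k2p_distance,
    load_vietnamellidae_distances,
    p_distance,
)

aligned_pair = st.integers(min_value=1, max_value=120).flatmap(
    lambda n: st.tuples(st.text(alphabet="ACGT", min_size=n, max_size=n),
                        st.text(alphabet="ACGT", min_size=n, max_size=n)))

aligned_triple = st.integers(min_value=1, max_value=80).flatmap(
    lambda n: st.tuples(*[st.text(alphabet="ACGT", min_size=n, max_size=n)
                          for _ in range(3)]))


class TestPDistance:
    def test_identical(self):
        assert p_distance("ACGT", "ACGT") == 0.0

    def test_quarter(self):
        assert p_distance("AAAA", "AAAT") == pytest.approx(0.25)

    def test_pairwise_deletion(self):
        # gap site removed: 3 comparable sites, 1 difference
        assert p_distance("AG-A", "AATA") == pytest.approx(1 / 3)
        # the deleted site never counts as a difference
        assert p_distance("AA-A", "AATA") == 0.0

    def test_n_treated_like_gap(self):
        assert p_distance("AANA", "AATA") == pytest.approx(0.0)

    def test_no_comparable_sites(self):
        assert p_distance("--", "AA") is None

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            p_distance("AAA", "AAAA")

    @given(aligned_pair)
    def test_symmetry_and_identity(self, pair):
        a, b = pair
        assert p_distance(a, b) == p_distance(b, a)
        assert p_distance(a, a) == 0.0
        assert 0.0 <= p_distance(a, b) <= 1.0

    @given(aligned_triple)
    def test_triangle_inequality(self, triple):
        a, b, c = triple
        dab, dbc, dac = p_distance(a, b), p_distance(b, c), p_distance(a, c)
        assert dac <= dab + dbc + 1e-12


class TestK2P:
    def test_zero(self):
        assert k2p_distance("ACGT", "ACGT") == 0.0

    def test_matches_direct_formula(self):
        # 1000 sites: 100 transitions (A->G), 50 transversions (A->C)
        a = "A" * 1000
        b = "G" * 100 + "C" * 50 + "A" * 850
        P, Q = 0.1, 0.05
        expected = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
        assert k2p_distance(a, b) == pytest.approx(expected)

    def test_small_divergence_approaches_p(self):
        a = "A" * 1000
        b = "G" * 5 + "A" * 995
        p = p_distance(a, b)
        assert k2p_distance(a, b) == pytest.approx(p, abs=2 * p * p)

    def test_saturation_is_none(self):
        # every site a transition: 1 - 2P - Q <= 0
        assert k2p_distance("AAAA", "GGGG") is None


class TestDistanceMatrix:
    def test_identical_pair_zero_matrix(self):
        m = distance_matrix({"a": "ACGT", "b": "ACGT"})
        assert np.allclose(m.values, 0.0)

    def test_duplicate_labels_raise(self):
        with pytest.raises(ValueError, match="duplicate"):
            distance_matrix([("a", "ACGT"), ("a", "ACGT")])

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError, match="lengths differ"):
            distance_matrix({"a": "ACGT", "b": "ACG"})

    def test_symmetric_zero_diagonal(self, sim4):
        records, _ = sim4
        m = distance_matrix({r.id: r.sequence for r in records})
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 0.0)

    def test_tsv_roundtrip(self, tmp_path):
        m, _ = load_vietnamellidae_distances()
        p = tmp_path / "m.tsv"
        m.write_tsv(p)
        back = DistanceMatrix.read_tsv(p)
        assert back.labels == m.labels
        assert np.allclose(back.values, m.values)

    def test_mega_lower_triangle(self, tmp_path):
        m, _ = load_vietnamellidae_distances()
        p = tmp_path / "m.txt"
        m.write_mega_lower(p)
        lines = p.read_text().splitlines()
        assert len(lines) == 6
        assert lines[0].split("\t") == ["1", "HM067837"]
        assert lines[5].split("\t")[2:] == \
            ["0.140", "0.211", "0.190", "0.148", "0.149"]


class TestFixture:
    def test_summary_matches_published_range(self):
        m, _ = load_vietnamellidae_distances()
        s = m.summary()
        assert s["n_pairs"] == 15
        assert s["min"] == pytest.approx(0.001)
        assert s["max"] == pytest.approx(0.211)
        assert s["mean"] == pytest.approx(2.338 / 15)

    def test_morphospecies_map(self):
        _, morpho = load_vietnamellidae_distances()
        assert sum(v == "Vietnamella sinensis" for v in morpho.values()) == 4


class TestDelimit:
    def test_fixture_at_007(self):
        m, morpho = load_vietnamellidae_distances()
        res = delimit(m, t_intra=0.07, morphospecies=morpho)
        assert sorted(map(sorted, res.clusters)) == sorted([
            ["CN", "HM067837", "TL"], ["MT-2014"], ["JZ-2021"], ["QY"]])
        assert res.flags[("HM067837", "QY")] == "cryptic_candidate"
        assert res.flags[("HM067837", "MT-2014")] == "distinct"
        hm = res.cluster_of("HM067837")
        qy = res.cluster_of("QY")
        d, pair = res.between_min[tuple(sorted((hm, qy)))]
        assert d == pytest.approx(0.140)

    def test_all_zero_matrix_single_cluster(self):
        m = DistanceMatrix(labels=["a", "b", "c"], values=np.zeros((3, 3)))
        res = delimit(m, t_intra=0.07)
        assert res.clusters == [["a", "b", "c"]]
        assert set(res.flags.values()) == {"conspecific"}

    def test_threshold_is_strict(self):
        v = np.array([[0.0, 0.07], [0.07, 0.0]])
        res = delimit(DistanceMatrix(labels=["a", "b"], values=v), 0.07)
        assert len(res.clusters) == 2

    def test_label_order_invariance(self):
        m, morpho = load_vietnamellidae_distances()
        perm = ["QY", "TL", "MT-2014", "HM067837", "JZ-2021", "CN"]
        res1 = delimit(m, 0.07, morpho)
        res2 = delimit(m.subset(perm), 0.07, morpho)
        canon = lambda clusters: sorted(tuple(sorted(c)) for c in clusters)
        assert canon(res1.clusters) == canon(res2.clusters)
        assert {frozenset(k): v for k, v in res1.flags.items()} == \
            {frozenset(k): v for k, v in res2.flags.items()}

    def test_monotone_transform_invariance(self):
        m, _ = load_vietnamellidae_distances()
        # sqrt preserves the order and, suitably rescaled, the 0.07 cut
        cut = 0.07
        trans = np.sqrt(m.values)
        res1 = delimit(m, cut)
        res2 = delimit(DistanceMatrix(labels=m.labels, values=trans),
                       math.sqrt(cut))
        canon = lambda clusters: sorted(tuple(sorted(c)) for c in clusters)
        assert canon(res1.clusters) == canon(res2.clusters)

    def test_without_morphospecies_all_distinct(self):
        m, _ = load_vietnamellidae_distances()
        res = delimit(m, 0.07)
        assert "cryptic_candidate" not in res.flags.values()

    def test_undefined_entries_raise(self):
        v = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="undefined"):
            delimit(DistanceMatrix(labels=["a", "b"], values=v), 0.07)

    def test_bad_threshold_raises(self):
        m, _ = load_vietnamellidae_distances()
        with pytest.raises(ValueError, match="t_intra"):
            delimit(m, 1.5)

    def test_planted_two_species_recovered(self):
        from mitocomp.simulate import (SimParams, planted_partition_tree,
                                       simulate)
        part = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        tree = planted_partition_tree(part, intra=0.01, inter=0.15)
        records, gt = simulate(SimParams(tree=tree, species_partition=part,
                                         seed=3))
        m = distance_matrix({r.id: r.sequence for r in records})
        res = delimit(m, t_intra=0.07)
        assert sorted(map(sorted, res.clusters)) == [["a1", "a2"],
                                                     ["b1", "b2"]]


class TestGlobalAlign:
    def test_simple_gap(self):
        a, b = global_align("ACGTACGT", "ACGACGT")
        assert len(a) == len(b)
        assert a.replace("-", "") == "ACGTACGT"
        assert b.replace("-", "") == "ACGACGT"

    def test_length_cap(self):
        with pytest.raises(ValueError, match="2000"):
            global_align("A" * 2001, "A" * 10)
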