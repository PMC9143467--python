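import numpy as np
import pytest

import dendropy

from mitocomp.distances import DistanceMatrix, distance_matrix, \
    load_vietnamellidae_distances
from mitocomp.io import PCG, extract_feature_seq
from mitocomp.supermatrix import (
    build_pcg12,
    clade_check,
    nj_tree,
    write_partition_file,
    write_supermatrix_fasta,
    write_supermatrix_phylip,
)


def _gene_alignments_from_sim(records):
    """Trivial per-gene 'alignments' (simulated records share coordinates)."""
    out = {}
    for f in records[0].features_of(PCG):
        block = {}
        for rec in records:
            seq = extract_feature_seq(rec, rec.feature(f.name))
            block[rec.id] = seq[:len(seq) - len(seq) % 3]
        out[f.name] = block
    return out


class TestBuildPcg12:
    def test_position_filtering_indices(self):
        sm = build_pcg12({"ND2": {"a": "ABCDEFGHI"}}, positions=(1, 2))
        # 9 columns -> keep 1,2,4,5,7,8 (1-based)
        assert sm.concatenated["a"] == "ABDEGH"

    def test_partition_table_additivity(self):
        genes = {"ND2": {"a": "A" * 900, "b": "C" * 900},
                 "COI": {"a": "G" * 450, "b": "T" * 450}}
        sm = build_pcg12(genes, positions=(1, 2))
        assert sm.partition_table == {"ND2": (1, 600), "COI": (601, 900)}
        assert sm.length == 900

    def test_all_positions_is_identity(self):
        genes = {"ND2": {"a": "ACGTTGCAA"}}
        sm = build_pcg12(genes, positions=(1, 2, 3))
        assert sm.concatenated["a"] == "ACGTTGCAA"

    def test_not_divisible_names_gene(self):
        with pytest.raises(ValueError, match="COI"):
            build_pcg12({"COI": {"a": "ACGT"}})

    def test_missing_taxon_padded_with_warning(self):
        genes = {"ND2": {"a": "ACG", "b": "ACG"}, "COI": {"a": "TTT"}}
        with pytest.warns(UserWarning, match="missing gene"):
            sm = build_pcg12(genes, positions=(1, 2))
        assert sm.concatenated["b"] == "AC--"

    def test_bad_positions_raise(self):
        with pytest.raises(ValueError, match="positions"):
            build_pcg12({"ND2": {"a": "ACG"}}, positions=(0, 4))

    def test_canonical_gene_order(self, sim4):
        records, _ = sim4
        sm = build_pcg12(_gene_alignments_from_sim(records))
        assert list(sm.partition_table) == [
            "ND2", "COI", "COII", "ATP8", "ATP6", "COIII", "ND3", "ND5",
            "ND4", "ND4L", "ND6", "CytB", "ND1"]

    def test_third_position_saturation(self, sim4):
        # generator third-position rate is 5x: dropping position 3 must
        # lower the mean pairwise distance
        records, _ = sim4
        genes = _gene_alignments_from_sim(records)
        sm12 = build_pcg12(genes, positions=(1, 2))
        sm123 = build_pcg12(genes, positions=(1, 2, 3))
        d12 = distance_matrix(sm12.concatenated).summary()["mean"]
        d123 = distance_matrix(sm123.concatenated).summary()["mean"]
        assert d12 < d123

    def test_writers(self, tmp_path):
        genes = {"ND2": {"a": "ACGACG", "b": "TTTTTT"}}
        sm = build_pcg12(genes, positions=(1, 2))
        write_supermatrix_fasta(sm, tmp_path / "s.fasta")
        write_supermatrix_phylip(sm, tmp_path / "s.phy")
        write_partition_file(sm, tmp_path / "p.txt")
        assert (tmp_path / "s.fasta").read_text() == ">a\nACAC\n>b\nTTTT\n"
        assert (tmp_path / "s.phy").read_text().splitlines()[0] == "2 4"
        assert (tmp_path / "p.txt").read_text() == "DNA, ND2 = 1-4\n"


def _random_additive_case(rng, n):
    """Random binary tree -> (newick, its additive distance matrix)."""
    labels = [f"t{i}" for i in range(n)]
    from mitocomp.simulate import random_tree
    nwk = random_tree(labels, rng, branch_scale=0.1)
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    vals = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                d = pdm.distance(tns.get_taxon(a), tns.get_taxon(b))
                vals[i, j] = vals[j, i] = d
    return tree, DistanceMatrix(labels=labels, values=vals)


class TestNjTree:
    def test_three_taxon_closed_form(self):
        vals = np.array([[0.0, 0.3, 0.4],
                         [0.3, 0.0, 0.5],
                         [0.4, 0.5, 0.0]])
        tree = nj_tree(DistanceMatrix(labels=["a", "b", "c"], values=vals))
        lengths = {leaf.taxon.label: leaf.edge.length
                   for leaf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.3)

    def test_too_few_taxa(self):
        vals = np.zeros((2, 2))
        with pytest.raises(ValueError, match="3 taxa"):
            nj_tree(DistanceMatrix(labels=["a", "b"], values=vals))

    def test_undefined_entries_raise(self):
        vals = np.full((3, 3), np.nan)
        np.fill_diagonal(vals, 0.0)
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(DistanceMatrix(labels=["a", "b", "c"], values=vals))

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_exact_recovery_on_additive_matrices(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(10):
            true_tree, m = _random_additive_case(rng, n)
            est = nj_tree(m)
            est2 = dendropy.Tree.get(
                data=est.as_string(schema="newick"), schema="newick",
                taxon_namespace=true_tree.taxon_namespace)
            true_tree.encode_bipartitions()
            est2.encode_bipartitions()
            rf = dendropy.calculate.treecompare.symmetric_difference(
                true_tree, est2)
            assert rf == 0
            # additive input -> patristic distances reproduced exactly
            pdm = est2.phylogenetic_distance_matrix()
            tns = true_tree.taxon_namespace
            for i, a in enumerate(m.labels):
                for b in m.labels[i + 1:]:
                    assert pdm.distance(
                        tns.get_taxon(a), tns.get_taxon(b)) == pytest.approx(
                        m.get(a, b), abs=1e-9)

    def test_deterministic(self):
        m, _ = load_vietnamellidae_distances()
        t1 = nj_tree(m).as_string(schema="newick")
        t2 = nj_tree(m).as_string(schema="newick")
        assert t1 == t2

    def test_fixture_subset_topology(self):
        # QY must attach outside the ((CN,TL),HM067837) group
        m, _ = load_vietnamellidae_distances()
        tree = nj_tree(m.subset(["CN", "TL", "HM067837", "QY"]))
        assert clade_check(tree, ["CN", "TL"])
        assert clade_check(tree, ["CN", "TL", "HM067837"])
        assert not clade_check(tree, ["QY", "CN"])

    def test_newick_roundtrip_idempotent(self, tmp_path):
        m, _ = load_vietnamellidae_distances()
        s1 = nj_tree(m).as_string(schema="newick")
        tree = dendropy.Tree.get(data=s1, schema="newick")
        assert tree.as_string(schema="newick") == s1


class TestCladeCheck:
    @pytest.fixture()
    def tree(self):
        return dendropy.Tree.get(
            data="((a:1,b:1):1,(c:1,d:1):1,e:1);", schema="newick")

    def test_true_clade(self, tree):
        assert clade_check(tree, ["a", "b"])

    def test_complement_side_counts(self, tree):
        assert clade_check(tree, ["c", "d", "e", "a", "b"])
        assert clade_check(tree, ["a", "b", "e"]) == \
            clade_check(tree, ["c", "d"])

    def test_non_clade(self, tree):
        assert not clade_check(tree, ["a", "c"])

    def test_single_tip_and_full_set(self, tree):
        assert clade_check(tree, ["a"])
        assert clade_check(tree, ["a", "b", "c", "d", "e"])

    def test_unknown_label_raises(self, tree):
        with pytest.raises(ValueError, match="not in tree"):
            clade_check(tree, ["zzz"])
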