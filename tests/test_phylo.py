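"""Masked comparison, private variants, haplogroup calls and NJ trees."""

import dendropy
import numpy as np
import pytest

from palaeomito.errors import (
    ConfigError,
    MissingTaxonError,
    TreeError,
    UndefinedEstimateError,
    ValidationError,
)
from palaeomito.fixtures import (
    L0D2C1C_DEFINING_LABELS,
    NAM_PAIR_DIFFERENCE_LABEL,
    STHE_PRIVATE_VARIANT_LABELS,
)
from palaeomito.phylo import (
    DistanceMatrix,
    HaplogroupNode,
    classify_haplogroup,
    nj_tree,
    p_distance_matrix,
    pairwise_comparison,
    private_variants,
    read_haplogroup_tree_tsv,
    write_haplogroup_tree_tsv,
)
from palaeomito.reference import (
    CODING_REGION,
    GenomeRecord,
    RegionMask,
    Variant,
    apply_variants,
)


class TestPairwiseComparison:
    def test_identical_genomes(self, study_fixture):
        g = study_fixture.genome("StHe_like")
        cmp = pairwise_comparison(g, g, study_fixture.mask)
        assert cmp.similarity == 1.0
        assert cmp.differences == []

    def test_ancient_vs_contemporary_counts_and_similarity(self, study_fixture):
        """The ancient genome differs from the closest contemporary genome
        at 9 of 16,531 masked-comparable sites (> 99.9% similar)."""
        cmp = pairwise_comparison(
            study_fixture.genome("StHe_like"),
            study_fixture.genome("NAM117_like"),
            study_fixture.mask,
        )
        assert cmp.n_compared == 16531
        assert cmp.n_diff == 9
        assert cmp.similarity > 0.999

    def test_symmetry_and_orientation(self, study_fixture):
        a = study_fixture.genome("StHe_like")
        b = study_fixture.genome("NAM168_like")
        ab = pairwise_comparison(a, b, study_fixture.mask)
        ba = pairwise_comparison(b, a, study_fixture.mask)
        assert ab.n_diff == ba.n_diff
        assert ab.similarity == ba.similarity
        assert {v.label for v in ba.differences} == {
            v.reversed().label for v in ab.differences
        }

    def test_all_n_genome_is_undefined(self, study_fixture):
        g = study_fixture.genome("StHe_like")
        blank = GenomeRecord("n", "N" * g.length)
        with pytest.raises(UndefinedEstimateError):
            pairwise_comparison(g, blank, study_fixture.mask)

    def test_masked_difference_is_invisible(self):
        a = GenomeRecord("a", "ACGTACGTAC")
        b = apply_variants(a, [Variant(3, "G", "T")], "b")
        masked = pairwise_comparison(a, b, RegionMask([(3, 3)]))
        assert masked.n_diff == 0
        assert masked.n_compared == 9


class TestPrivateVariants:
    def test_ancient_genome_has_the_nine_printed_variants(self, study_fixture):
        clade = [
            study_fixture.genome("StHe_like"),
            study_fixture.genome("NAM117_like"),
            study_fixture.genome("NAM168_like"),
        ]
        got = [v.label for v in private_variants(clade, "StHe_like", study_fixture.mask)]
        assert got == STHE_PRIVATE_VARIANT_LABELS

    def test_contemporary_pair_differs_at_single_site(self, study_fixture):
        clade = [
            study_fixture.genome("StHe_like"),
            study_fixture.genome("NAM117_like"),
            study_fixture.genome("NAM168_like"),
        ]
        got = [v.label for v in private_variants(clade, "NAM168_like", study_fixture.mask)]
        assert got == [NAM_PAIR_DIFFERENCE_LABEL]

    def test_identical_genomes_have_no_private_variants(self, study_fixture):
        g = study_fixture.genome("NAM117_like")
        clade = [g, GenomeRecord("copy1", g.sequence), GenomeRecord("copy2", g.sequence)]
        assert private_variants(clade, "copy1", study_fixture.mask) == []

    def test_hotspot_site_never_reported(self, study_fixture):
        ref = study_fixture.reference
        g = GenomeRecord("a", ref.sequence)
        pos = 310  # inside the 303-315 poly-C hotspot
        mutant = apply_variants(
            g, [Variant(pos, ref.base(pos), "ACGT"[("ACGT".index(ref.base(pos)) + 1) % 4])], "m"
        )
        clade = [mutant, g, GenomeRecord("c", g.sequence)]
        assert private_variants(clade, "m", study_fixture.mask) == []

    def test_unknown_focal_raises(self, study_fixture):
        clade = [study_fixture.genome("StHe_like"), study_fixture.genome("NAM117_like")]
        with pytest.raises(MissingTaxonError):
            private_variants(clade, "nope", study_fixture.mask)


class TestHaplogroupClassification:
    def test_ancient_genome_called_into_new_subclade(self, study_fixture):
        """The ancient genome descends to L0d2c1c, matching both defining
        variants C10822A and C16355T."""
        call = classify_haplogroup(
            study_fixture.genome("StHe_like"),
            study_fixture.tree,
            GenomeRecord("root", study_fixture.reference.sequence),
            study_fixture.mask,
        )
        assert call.call == "L0d2c1c"
        assert call.path == ["root", "L0d2c", "L0d2c1", "L0d2c1c"]
        assert call.node_support["L0d2c1c"] == (2, 2)
        assert not call.ambiguous
        labels = {v.label for v in study_fixture.defining_variants["L0d2c1c"]}
        assert labels == set(L0D2C1C_DEFINING_LABELS)

    def test_root_reference_stays_at_root(self, study_fixture):
        call = classify_haplogroup(
            GenomeRecord("root", study_fixture.reference.sequence),
            study_fixture.tree,
            GenomeRecord("root", study_fixture.reference.sequence),
            study_fixture.mask,
        )
        assert call.call == "root"
        assert call.path == ["root"]

    def test_intermediate_genome_stops_at_deepest_supported_node(self, study_fixture):
        call = classify_haplogroup(
            study_fixture.genome("ancestral_L0d2c1"),
            study_fixture.tree,
            GenomeRecord("root", study_fixture.reference.sequence),
            study_fixture.mask,
        )
        assert call.call == "L0d2c1"

    def test_duplicate_node_names_rejected(self, study_fixture):
        tree = HaplogroupNode(
            "root", [], [HaplogroupNode("A", []), HaplogroupNode("A", [])]
        )
        with pytest.raises(TreeError):
            classify_haplogroup(
                study_fixture.genome("StHe_like"),
                tree,
                GenomeRecord("root", study_fixture.reference.sequence),
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_root_to_leaf_construction_always_calls_the_leaf(self, study_fixture, seed):
        """Applying a random root-to-leaf defining-variant path to the root
        reference always classifies to that leaf."""
        rng = np.random.default_rng(1000 + seed)
        ref = study_fixture.reference
        used = set()

        def fresh_variants(n):
            out = []
            while len(out) < n:
                p = int(rng.integers(600, 16000))
                if p in used:
                    continue
                used.add(p)
                b = ref.base(p)
                out.append(Variant(p, b, "ACGT"[("ACGT".index(b) + 1 + int(rng.integers(0, 3))) % 4]))
            return out

        def build(depth, prefix):
            children = []
            if depth < 3:
                for c in range(int(rng.integers(1, 4))):
                    children.append(build(depth + 1, f"{prefix}{c}"))
            return HaplogroupNode(prefix, fresh_variants(int(rng.integers(1, 4))), children)

        tree = HaplogroupNode("root", [], [build(1, "n")])
        # pick a random leaf and accumulate its path variants
        node, variants = tree, []
        while node.children:
            node = node.children[int(rng.integers(0, len(node.children)))]
            variants.extend(node.defining_variants)
        genome = apply_variants(GenomeRecord("g", ref.sequence), variants)
        call = classify_haplogroup(
            genome, tree, GenomeRecord("root", ref.sequence), study_fixture.mask
        )
        assert call.call == node.name

    def test_tree_tsv_round_trip(self, study_fixture, tmp_path):
        path = tmp_path / "tree.tsv"
        write_haplogroup_tree_tsv(study_fixture.tree, path)
        back = read_haplogroup_tree_tsv(path)
        orig = {
            n.name: [v.label for v in n.defining_variants]
            for n in study_fixture.tree.walk()
        }
        rt = {n.name: [v.label for v in n.defining_variants] for n in back.walk()}
        assert rt == orig


class TestDistances:
    def test_identical_genomes_give_zero_matrix(self, study_fixture):
        g = study_fixture.genome("NAM117_like")
        dm = p_distance_matrix(
            [g, GenomeRecord("b", g.sequence), GenomeRecord("c", g.sequence)],
            study_fixture.mask,
        )
        assert (dm.values == 0).all()

    def test_comparable_site_counts_match_mask_arithmetic(self, study_fixture):
        """N-free genomes compare over 16,531 sites genome-wide and 15,447
        in the coding region."""
        a = study_fixture.genome("StHe_like")
        b = study_fixture.genome("NAM117_like")
        whole = pairwise_comparison(a, b, study_fixture.mask)
        coding = pairwise_comparison(a, b, study_fixture.mask, window=CODING_REGION)
        assert whole.n_compared == 16531
        assert coding.n_compared == 15447

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


def _tree_distance_matrix(tree, labels):
    pdm = tree.phylogenetic_distance_matrix()
    ns = tree.taxon_namespace
    return np.array(
        [[pdm.distance(ns.get_taxon(a), ns.get_taxon(b)) for b in labels] for a in labels]
    )


def _random_additive_tree(labels, rng):
    ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=ns.get_taxon(lab))
        node.edge.length = rng.uniform(0.1, 1.0)
        nodes.append(node)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = rng.uniform(0.1, 1.0)
        parent.add_child(nodes[j])
        parent.add_child(nodes[i])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    for n in nodes:
        tree.seed_node.add_child(n)
    tree.update_bipartitions()
    return tree


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 5.0, 9.0], [5.0, 0.0, 10.0], [9.0, 10.0, 0.0]])
        nwk = nj_tree(DistanceMatrix(["A", "B", "C"], d))
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths == {"A": pytest.approx(2.0), "B": pytest.approx(3.0), "C": pytest.approx(7.0)}

    @pytest.mark.parametrize("seed", range(5))
    def test_additive_matrices_recover_generating_tree_exactly(self, seed):
        """NJ on path distances of a random 5-8 taxon tree reproduces its
        topology (RF = 0) and every pairwise path distance."""
        rng = np.random.default_rng(seed)
        labels = [f"T{k}" for k in range(int(rng.integers(5, 9)))]
        true_tree = _random_additive_tree(labels, rng)
        D = _tree_distance_matrix(true_tree, labels)
        nwk = nj_tree(DistanceMatrix(labels, D))
        nj = dendropy.Tree.get(
            data=nwk, schema="newick", taxon_namespace=true_tree.taxon_namespace
        )
        nj.update_bipartitions()
        assert (
            dendropy.calculate.treecompare.symmetric_difference(true_tree, nj) == 0
        )
        D2 = _tree_distance_matrix(nj, labels)
        assert np.abs(D - D2).max() < 1e-8

    def test_agrees_with_independent_nj_implementation(self):
        """Same topology as scikit-bio's neighbor joining on an additive
        matrix."""
        import skbio

        rng = np.random.default_rng(12)
        labels = [f"T{k}" for k in range(6)]
        true_tree = _random_additive_tree(labels, rng)
        D = _tree_distance_matrix(true_tree, labels)
        ours = dendropy.Tree.get(
            data=nj_tree(DistanceMatrix(labels, D)),
            schema="newick",
            taxon_namespace=true_tree.taxon_namespace,
        )
        theirs_nwk = str(skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels)))
        theirs = dendropy.Tree.get(
            data=theirs_nwk, schema="newick", taxon_namespace=true_tree.taxon_namespace
        )
        ours.update_bipartitions()
        theirs.update_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(ours, theirs) == 0

    def test_fixture_clade_is_monophyletic_against_outgroup(self, study_fixture):
        """The ancient + contemporary subclade groups together to the
        exclusion of the sister subclade and the outgroup."""
        names = ["StHe_like", "NAM117_like", "NAM168_like", "L0d2c1a_like", "outgroup"]
        dm = p_distance_matrix(
            [study_fixture.genome(n) for n in names], study_fixture.mask
        )
        nwk = nj_tree(dm, outgroup="outgroup")
        tree = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
        tree.is_rooted = True
        clade = {"StHe_like", "NAM117_like", "NAM168_like"}
        mrca = tree.mrca(taxon_labels=clade)
        assert {leaf.taxon.label for leaf in mrca.leaf_iter()} == clade

    def test_outgroup_must_exist(self):
        d = np.zeros((3, 3))
        with pytest.raises(MissingTaxonError):
            nj_tree(DistanceMatrix(["a", "b", "c"], d), outgroup="zzz")

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ConfigError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))
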