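"""Purity, CCF, trunk/branch partition, and maximum-parsimony trees."""

import numpy as np
import pandas as pd
import pytest

from cstyper.clonality import (
    build_parsimony_tree, compute_ccf, estimate_purity, partition_trunk_branch,
    place_drivers,
)
from cstyper.simulate import GeneratorConfig, generate_biphasic, generate_multiregion
from cstyper.variants import CopyNumberSegment


def seg(baf, sid="S1"):
    return CopyNumberSegment(sid, "chr22", 1, 10_000_000, -1.0, 1, baf=baf)


class TestEstimatePurity:
    def test_pure_tumor_baf_one(self):
        assert estimate_purity(segments=[seg(1.0)]).purity == pytest.approx(1.0)

    def test_mixture_algebra_baf_two_thirds(self):
        # tumor keeps one A copy, normal contributes A+B: BAF(A) = 1/(2-p)
        assert estimate_purity(segments=[seg(2 / 3)]).purity == pytest.approx(0.5)

    def test_no_loh_signal_is_unestimable(self):
        with pytest.raises(ValueError, match="unestimable"):
            estimate_purity(segments=[seg(0.5)])

    def test_median_across_regions(self):
        est = estimate_purity(segments=[seg(2 / 3), seg(1.0), seg(0.8)])
        assert est.n_loh_regions == 3
        assert est.purity == pytest.approx(2 - 1 / 0.8)

    def test_copy_neutral_model(self):
        est = estimate_purity(segments=[seg(0.75)], model="copy_neutral")
        assert est.purity == pytest.approx(0.5)


class TestComputeCcf:
    def test_heterozygous_clonal_in_pure_diploid(self):
        ann = compute_ccf(0.5, 1.0, 2)
        assert ann.ccf == pytest.approx(1.0) and ann.clonal

    def test_forward_mixture_half_purity(self):
        ann = compute_ccf(0.25, 0.5, 2)
        assert ann.ccf == pytest.approx(1.0)

    @pytest.mark.parametrize("ccf, clonal", [(0.80, True), (0.79, False)])
    def test_clonality_boundary(self, ccf, clonal):
        ann = compute_ccf(vaf=ccf * 0.5, purity=1.0, tumor_cn=2, multiplicity=1)
        assert ann.ccf == pytest.approx(ccf)
        assert ann.clonal is clonal

    def test_multiplicity_resolution_prefers_ccf_near_one(self):
        # pure tumor, CN 4: vaf 0.5 is best explained by multiplicity 2
        ann = compute_ccf(0.5, 1.0, tumor_cn=4)
        assert ann.multiplicity == 2 and ann.ccf == pytest.approx(1.0)

    def test_invalid_purity_rejected(self):
        with pytest.raises(ValueError):
            compute_ccf(0.5, 0.0, 2)


class TestTrunkBranchPartition:
    def test_identical_components_all_trunk(self):
        part = partition_trunk_branch({"a", "b"}, {"a", "b"})
        assert part["trunk_fraction"] == 1.0
        assert part["n_branch_a"] == part["n_branch_b"] == 0

    def test_printed_cnl_fraction(self):
        shared = {f"m{i}" for i in range(15)}
        part = partition_trunk_branch(shared | {"priv"}, shared)
        assert part["n_trunk"] == 15
        assert part["trunk_fraction"] == pytest.approx(15 / 16, abs=5e-4)

    def test_disjoint_components(self):
        part = partition_trunk_branch({"a"}, {"b"})
        assert part["n_trunk"] == 0

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError):
            partition_trunk_branch(set(), set())


class TestParsimonyTree:
    def test_two_regions_match_partition(self):
        M = pd.DataFrame(
            [[1, 1, 1, 0], [1, 1, 0, 1]], index=["Ca", "Sa"],
            columns=["m1", "m2", "m3", "m4"],
        )
        tree = build_parsimony_tree(M)
        part = partition_trunk_branch({"m1", "m2", "m3"}, {"m1", "m2", "m4"})
        lengths = {tree.leaf_names.get(c, "trunk"): ln
                   for (p, c), ln in tree.edge_lengths.items()}
        assert lengths["Ca"] == part["n_branch_a"]
        assert lengths["Sa"] == part["n_branch_b"]
        assert lengths["trunk"] == part["n_trunk"]

    def test_perfect_phylogeny_length_equals_variable_characters(self):
        M = np.array([
            [1, 1, 0, 0, 1],
            [1, 1, 0, 0, 0],
            [1, 0, 1, 0, 0],
            [1, 0, 0, 1, 0],
        ])
        tree = build_parsimony_tree(M)
        assert tree.parsimony_length == M.shape[1]

    def test_identical_regions_zero_terminal_branches(self):
        M = np.array([[1, 1, 0], [1, 1, 0]])
        tree = build_parsimony_tree(M)
        terminal = [ln for (p, c), ln in tree.edge_lengths.items()
                    if c in tree.leaf_names and c != tree.root]
        assert terminal == [0, 0]

    def test_too_many_regions_guided_to_heuristic(self):
        with pytest.raises(ValueError, match="exceeds"):
            build_parsimony_tree(np.ones((9, 3), dtype=int))

    @pytest.mark.parametrize("seed", range(12))
    def test_minimum_length_matches_brute_force(self, seed, oracle):
        rng = np.random.default_rng(seed)
        n_regions = rng.integers(3, 7)
        n_chars = rng.integers(5, 31)
        M = (rng.random((n_regions, n_chars)) < 0.4).astype(int)
        tree = build_parsimony_tree(M)
        assert tree.parsimony_length == oracle.parsimony(M)
        assert sum(tree.edge_lengths.values()) == tree.parsimony_length

    def test_deterministic_output_on_ties(self):
        M = np.array([[1, 0], [0, 1], [1, 1]])
        t1 = build_parsimony_tree(M)
        t2 = build_parsimony_tree(M)
        assert t1.newick() == t2.newick()

    def test_newick_parses_with_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        M = np.array([[1, 1, 0], [1, 0, 1], [0, 1, 1]])
        tree = build_parsimony_tree(M)
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert {lf.taxon.label for lf in parsed.leaf_nodes()} == {"R1", "R2", "R3"}
        assert parsed.seed_node.label == "germline"  # outgroup as root label


class TestPlaceDrivers:
    def setup_method(self):
        self.M = pd.DataFrame(
            np.array([
                [1, 1, 0, 1],
                [1, 1, 0, 0],
                [1, 0, 1, 0],
                [1, 0, 0, 0],
            ]),
            index=["T1", "T2", "T3", "T4"],
            columns=["trunk_drv", "clade_drv", "private_drv", "t1_drv"],
        )
        self.tree = build_parsimony_tree(self.M)

    def test_ubiquitous_driver_on_trunk_edge(self):
        place_drivers(self.tree, ["trunk_drv"])
        (edge,) = self.tree.driver_placements["trunk_drv"].edges
        assert edge[0] == self.tree.root  # the edge leaving the germline root

    def test_private_driver_on_its_terminal_edge(self):
        ccf = {("private_drv", "T3"): 0.9}
        place_drivers(self.tree, ["private_drv"], ccf)
        placement = self.tree.driver_placements["private_drv"]
        (edge,) = placement.edges
        assert self.tree.leaf_names.get(edge[1]) == "T3"
        assert placement.clonal is True

    def test_clade_driver_on_internal_edge(self):
        place_drivers(self.tree, ["clade_drv"])
        (edge,) = self.tree.driver_placements["clade_drv"].edges
        assert edge[1] not in self.tree.leaf_names  # internal node

    def test_homoplastic_driver_flagged_on_all_gain_edges(self):
        M = pd.DataFrame(
            np.array([[1, 1], [0, 1], [1, 0], [0, 1]]),
            index=["T1", "T2", "T3", "T4"], columns=["homo", "x"],
        )
        tree = build_parsimony_tree(M)
        place_drivers(tree, ["homo"])
        placement = tree.driver_placements["homo"]
        assert placement.homoplasy
        assert len(placement.edges) >= 2

    def test_unknown_driver_rejected(self):
        with pytest.raises(KeyError):
            place_drivers(self.tree, ["nope"])


class TestGeneratorRoundTrips:
    def test_biphasic_trunk_fraction_recovered(self):
        cfg = GeneratorConfig(read_noise=False)
        ca, sa, truth = generate_biphasic(cfg, subtype="CNL", seed=3, n_mutations=16)
        part = partition_trunk_branch({v.key for v in ca}, {v.key for v in sa})
        assert part["n_trunk"] == truth["n_trunk"] == 15
        assert part["trunk_fraction"] == pytest.approx(truth["trunk_fraction_realized"])

    def test_biphasic_full_trunk_identical_components(self):
        cfg = GeneratorConfig(
            trunk_fraction={"CNL": 1.0, "CNH": 1.0, "POLE": 1.0, "MSI": 1.0}
        )
        ca, sa, _ = generate_biphasic(cfg, subtype="CNH", seed=1, n_mutations=20)
        assert {v.key for v in ca} == {v.key for v in sa}

    @pytest.mark.parametrize("n_regions", [2, 3, 5])
    def test_multiregion_topology_recovered(self, n_regions):
        matrix, truth = generate_multiregion(n_regions=n_regions, seed=n_regions)
        tree = build_parsimony_tree(matrix)
        assert tree.splits() == truth["splits"]  # Robinson-Foulds distance 0

    def test_multiregion_edge_counts_recovered(self):
        matrix, truth = generate_multiregion(n_regions=4, seed=9)
        tree = build_parsimony_tree(matrix)
        # recovered edge lengths keyed by the region set below each edge
        below = {}
        for (parent, child), ln in tree.edge_lengths.items():
            names = frozenset(
                tree.leaf_names[n] for n in _leaves_below(tree, child)
            )
            below[names] = ln
        for clade, count in truth["edge_counts"].items():
            assert below[frozenset(clade)] == count

    def test_root_edge_mutation_in_all_regions(self):
        matrix, truth = generate_multiregion(n_regions=3, seed=2, branch_mean=0.0)
        trunk_chars = matrix.loc[:, matrix.sum(axis=0) == matrix.shape[0]]
        assert trunk_chars.shape[1] == truth["edge_counts"][
            frozenset(truth["regions"])]


def _leaves_below(tree, node):
    kids = tree.children[node]
    if not kids:
        return {node}
    out = set()
    for k in kids:
        out |= _leaves_below(tree, k)
    return out
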