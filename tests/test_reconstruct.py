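"""Set-partition machinery, constraint clustering and multiplicity tables."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from protokaryo.core_io import ConfigurationError, Segmentation
from protokaryo.cvb import CVBConfig, assign_segments, build_count_tensor, cvb0_fit
from protokaryo.reconstruct import (
    ConstraintGraph,
    GroupContext,
    bell_number,
    build_constraints,
    build_group_context,
    cluster_segments,
    drop_small_clusters,
    enumerate_partitions,
    filter_subgroups,
    multiplicity_table,
    reconstruct_all,
    score_partition,
    select_optimal_partition,
)
from protokaryo.simulate import EvolutionConfig, simulate
from protokaryo.stats import hypergeom_tail


class TestBellNumbers:
    def test_first_values(self):
        assert [bell_number(n) for n in range(6)] == [1, 1, 2, 5, 15, 52]

    def test_enumeration_count_matches_bell(self):
        for n in range(1, 9):
            count = sum(1 for _ in enumerate_partitions(list(range(n))))
            assert count == bell_number(n)

    def test_twenty_one_segments(self):
        assert bell_number(21) == 474_869_816_156_751

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bell_number(-1)


class TestEnumeratePartitions:
    def test_three_items_give_five_partitions(self):
        parts = list(enumerate_partitions(["a", "b", "c"]))
        assert len(parts) == 5
        assert all(frozenset().union(*p) == {"a", "b", "c"} for p in parts)
        assert len({tuple(sorted(tuple(sorted(b)) for b in p)) for p in parts}) == 5

    def test_single_item(self):
        assert list(enumerate_partitions(["a"])) == [(frozenset(["a"]),)]

    def test_constrained_counts_match_bruteforce_filter(self, rng):
        for n in (4, 6, 8):
            items = list(range(n))
            forbidden = set()
            for _ in range(n):
                i, j = rng.choice(n, size=2, replace=False)
                forbidden.add(frozenset((int(i), int(j))))
            got = sum(1 for _ in enumerate_partitions(items, forbidden))
            want = 0
            for part in enumerate_partitions(items):
                ok = all(
                    not any(
                        frozenset((a, b)) in forbidden
                        for a in block
                        for b in block
                        if a < b
                    )
                    for block in part
                )
                want += ok
            assert got == want

    def test_forbidden_pair_never_cohabits(self):
        forb = {frozenset((0, 1))}
        for part in enumerate_partitions([0, 1, 2, 3], forb):
            for block in part:
                assert not {0, 1} <= set(block)

    def test_cap_refusal_mentions_count(self):
        with pytest.raises(ConfigurationError, match="enumeration cap"):
            list(enumerate_partitions(list(range(16)), max_items=15))


def toy_context():
    """Two species, 4 segments (2 per species), 2 true descendants.

    Segments 0,1 in species u; 10,11 in species v.  Truth: {0, 10} and
    {1, 11} are the two descendant chromosomes.
    """
    segment_genes = {
        0: [f"u0_{i}" for i in range(10)],
        1: [f"u1_{i}" for i in range(10)],
        10: [f"v0_{i}" for i in range(10)],
        11: [f"v1_{i}" for i in range(10)],
    }
    paralogues = {
        "u": {(f"u0_{i}", f"u1_{i}") for i in range(8)},
        "v": {(f"v0_{i}", f"v1_{i}") for i in range(8)},
    }
    orthologues = {
        ("u", "v"): {(f"u0_{i}", f"v0_{i}") for i in range(9)}
        | {(f"u1_{i}", f"v1_{i}") for i in range(9)},
    }
    return GroupContext(
        ancestral_chromosome=1,
        segment_species={0: "u", 1: "u", 10: "v", 11: "v"},
        segment_genes=segment_genes,
        genome_gene_counts={"u": 400, "v": 400},
        paralogues=paralogues,
        orthologues=orthologues,
    )


class TestConstraintsAndClustering:
    def test_paralogy_forbids_orthology_attracts(self):
        graph = build_constraints(toy_context())
        assert frozenset((0, 1)) in graph.forbidden
        assert frozenset((10, 11)) in graph.forbidden
        attracted = {frozenset((a, b)) for _, _, a, b in graph.attractions}
        assert frozenset((0, 10)) in attracted
        assert frozenset((1, 11)) in attracted

    def test_forbidden_wins_over_attraction(self):
        ctx = toy_context()
        # make segments 0 and 1 also strongly "orthologous" is impossible
        # within one species; instead verify the rule on the graph level
        graph = ConstraintGraph(
            nodes=[0, 1], forbidden={frozenset((0, 1))},
            attractions=[(1, 1e-20, 0, 1)],
        )
        clusters = cluster_segments(graph)
        assert sorted(map(sorted, clusters)) == [[0], [1]]

    def test_no_attractions_gives_singletons(self):
        graph = ConstraintGraph(nodes=[1, 2, 3], forbidden=set(), attractions=[])
        assert sorted(map(sorted, cluster_segments(graph))) == [[1], [2], [3]]

    def test_greedy_chain_respects_forbidden(self):
        # a-b then b-c by significance, a-c forbidden: {a,b} forms, c stays out
        graph = ConstraintGraph(
            nodes=["a", "b", "c"],
            forbidden={frozenset(("a", "c"))},
            attractions=[(1, 1e-10, "a", "b"), (1, 1e-8, "b", "c")],
        )
        clusters = cluster_segments(graph)
        assert sorted(map(sorted, clusters)) == [["a", "b"], ["c"]]

    def test_shared_linkage_group_attracts(self, clade_1r):
        from protokaryo.core_io import LinkageMarkerTable

        gene_table, pairs, _ = clade_1r
        seg = Segmentation.from_scaffolds(gene_table, ["spA", "spB"])
        tensor = build_count_tensor(gene_table, pairs, seg)
        res = cvb0_fit(tensor, CVBConfig(K=2, seed=0))
        asg = assign_segments(res)
        ctx = build_group_context(gene_table, pairs, seg, asg, 1)
        ids = [s for s in ctx.segment_ids if ctx.segment_species[s] == "spA"]
        scaf_of = {s.segment_id: s.scaffold for s in seg.segments}
        markers = LinkageMarkerTable(
            pd.DataFrame(
                {
                    "marker_id": ["m1", "m2"],
                    "species": ["spA", "spA"],
                    "scaffold": [scaf_of[ids[0]], scaf_of[ids[1]]],
                    "position": [0, 0],
                    "linkage_group": ["LG1", "LG1"],
                }
            )
        )
        bare = build_constraints(ctx, seg)
        with_markers = build_constraints(ctx, seg, markers, gene_table)
        marker_edges = {
            frozenset((a, b)) for t, _, a, b in with_markers.attractions if t == 3
        }
        assert frozenset((ids[0], ids[1])) in marker_edges or frozenset(
            (ids[0], ids[1])
        ) in bare.forbidden

    def test_same_scaffold_tier(self, clade_1r):
        gene_table, pairs, _ = clade_1r
        seg = Segmentation.from_scaffolds(gene_table, ["spA", "spB"])
        tensor = build_count_tensor(gene_table, pairs, seg)
        res = cvb0_fit(tensor, CVBConfig(K=2, seed=0))
        asg = assign_segments(res)
        ctx = build_group_context(gene_table, pairs, seg, asg, 1)
        graph = build_constraints(ctx, seg)
        assert graph.nodes


class TestDropSmall:
    def test_boundary_at_five_genes(self):
        ctx = GroupContext(
            ancestral_chromosome=1,
            segment_species={0: "u", 1: "u"},
            segment_genes={0: [f"a{i}" for i in range(4)],
                           1: [f"b{i}" for i in range(5)]},
            genome_gene_counts={"u": 100},
            paralogues={"u": set()},
            orthologues={},
        )
        kept = drop_small_clusters([frozenset([0]), frozenset([1])], ctx)
        assert kept == [frozenset([1])]

    def test_gene_conservation(self):
        ctx = GroupContext(
            ancestral_chromosome=1,
            segment_species={0: "u", 1: "u", 2: "u"},
            segment_genes={0: ["a"], 1: ["b", "c"], 2: list("defgh")},
            genome_gene_counts={"u": 100},
            paralogues={"u": set()},
            orthologues={},
        )
        clusters = [frozenset([0, 1]), frozenset([2])]
        kept = drop_small_clusters(clusters, ctx)
        total_in = sum(ctx.n_genes(s) for c in clusters for s in c)
        total_kept = sum(ctx.n_genes(s) for c in kept for s in c)
        assert total_in - total_kept == 3


class TestScorePartition:
    def test_no_homology_scores_neutral(self):
        ctx = GroupContext(
            ancestral_chromosome=1,
            segment_species={0: "u", 1: "u"},
            segment_genes={0: ["a", "b"], 1: ["c", "d"]},
            genome_gene_counts={"u": 50},
            paralogues={"u": set()},
            orthologues={},
        )
        assert score_partition([frozenset([0]), frozenset([1])], ctx) == 1.0

    def test_matches_hand_computed_factor_product(self):
        ctx = toy_context()
        part = [frozenset([0, 10]), frozenset([1, 11])]
        got = score_partition(part, ctx)
        # hand computation, factor by factor
        expect = 1.0
        for sp in ("u", "v"):
            g_cs = math.comb(20, 2)
            p_cs = 8
            n_s = 10 * 10          # inter-block gene pairs within the species
            x_s = 8                # all paralogues are inter-block in truth
            expect *= hypergeom_tail(g_cs, p_cs, n_s, x_s)
        g_cst, o_cst = 20 * 20, 18
        n_st = 10 * 10 + 10 * 10   # same-block cross-species gene pairs
        x_st = 18
        expect *= hypergeom_tail(g_cst, o_cst, n_st, x_st)
        assert got == pytest.approx(expect, rel=1e-9)

    def test_true_partition_beats_every_alternative(self):
        ctx = toy_context()
        truth = (frozenset([0, 10]), frozenset([1, 11]))
        true_score = score_partition(truth, ctx)
        for part in enumerate_partitions([0, 1, 10, 11]):
            if set(map(frozenset, part)) == set(truth):
                continue
            assert score_partition(part, ctx) > true_score

    def test_gnathostome_all_red_equals_cyclostome(self):
        ctx = toy_context()
        part = [frozenset([0, 10]), frozenset([1, 11])]
        assert score_partition(part, ctx, "cyclostome") == score_partition(
            part, ctx, "gnathostome", red_pair_rule="all"
        )


class TestSelectOptimal:
    def test_single_cluster_single_chromosome(self):
        ctx = toy_context()
        blocks, _ = select_optimal_partition([frozenset([0, 1, 10, 11])], ctx)
        assert blocks == (frozenset([0, 1, 10, 11]),)

    def test_recovers_true_descendants(self):
        ctx = toy_context()
        graph = build_constraints(ctx)
        clusters = cluster_segments(graph)
        blocks, _ = select_optimal_partition(
            clusters, ctx, forbidden=graph.forbidden
        )
        assert set(blocks) == {frozenset([0, 10]), frozenset([1, 11])}

    def test_beats_random_valid_partitions(self, rng):
        ctx = toy_context()
        best, best_score = select_optimal_partition(
            [frozenset([s]) for s in ctx.segment_ids], ctx
        )
        parts = list(enumerate_partitions(ctx.segment_ids))
        for i in rng.choice(len(parts), size=min(100, len(parts)), replace=True):
            assert best_score <= score_partition(parts[int(i)], ctx) + 1e-15


class TestFilterSubgroups:
    def make_proto(self):
        return pd.DataFrame(
            {
                "proto_chromosome": ["p1", "p1", "p1", "p2", "p2"],
                "ancestral_chromosome": [1] * 5,
                "segment_id": [0, 1, 2, 3, 4],
                "species": ["a", "b", "c", "a", "b"],
                "n_genes": [10, 10, 10, 10, 10],
                "flagged": [False] * 5,
            }
        )

    def test_two_species_subgroup_removed_three_kept(self):
        out = filter_subgroups(self.make_proto(), min_species=3)
        assert set(out["proto_chromosome"]) == {"p1"}

    def test_removed_totals_consistent(self):
        proto = self.make_proto()
        out = filter_subgroups(proto, min_species=3)
        assert proto["n_genes"].sum() - out["n_genes"].sum() == 20


class TestMultiplicity:
    def run_pipeline(self, branches, seed, k_anc=3):
        cfg = EvolutionConfig(
            k_anc=k_anc, genes_per_chromosome=80,
            branches=branches,
            roles={"ref": "reference", "x": "post_wgd", "y": "post_wgd"},
            retention={"ref": 1.0, "x": 0.75, "y": 0.75}, seed=seed,
        )
        gene_table, pairs, truth = simulate(cfg)
        seg = Segmentation.from_scaffolds(gene_table, ["x", "y"])
        tensor = build_count_tensor(gene_table, pairs, seg)
        res = cvb0_fit(tensor, CVBConfig(K=k_anc, seed=0))
        asg = assign_segments(res)
        return reconstruct_all(gene_table, pairs, seg, asg, species=["x", "y"])

    def test_sixfold_history_gives_multiplicity_six(self):
        wgd = [("tetraploidize",), ("hexaploidize",), ("invert", 1.0)]
        _, mult = self.run_pipeline({"ref": [], "x": wgd, "y": wgd}, seed=3)
        assert mult["multiplicity"].tolist() == [6, 6, 6]

    def test_pure_1r_gives_multiplicity_two(self):
        wgd = [("tetraploidize",), ("invert", 1.0)]
        _, mult = self.run_pipeline({"ref": [], "x": wgd, "y": wgd}, seed=5)
        assert mult["multiplicity"].tolist() == [2, 2, 2]

    def test_fractions_sum_to_post_wgd_share(self):
        wgd = [("tetraploidize",)]
        proto, mult = self.run_pipeline({"ref": [], "x": wgd, "y": wgd}, seed=7)
        # every post-WGD gene is in exactly one proto-chromosome
        assert mult["n_genes"].sum() == proto["n_genes"].sum()
        fractions = multiplicity_table(proto)["fraction"]
        assert fractions.sum() == pytest.approx(1.0)

    def test_unlabelled_block_rejected(self):
        bad = pd.DataFrame(
            {"proto_chromosome": ["p"], "ancestral_chromosome": [np.nan],
             "segment_id": [0], "species": ["a"], "n_genes": [5],
             "flagged": [False]}
        )
        with pytest.raises(ValueError):
            multiplicity_table(bad)
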