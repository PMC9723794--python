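"""Orthology pipeline: RBM rule, OG clustering, partition, trees."""

import numpy as np
import pandas as pd
import pytest

from degradomics import synthetic as sd
from degradomics.pangenome import (
    OrthologGroup,
    RbmEdge,
    SearchHit,
    all_vs_all,
    center_star_align,
    cluster_genomes_by_variable_genes,
    cluster_ogs,
    core_concat_nj,
    core_og_alignments,
    find_rbms,
    p_distance_matrix,
    partition_pangenome,
    variable_presence,
)


def _hit(qg, qgene, sg, sgene, sim, cov=1.0, score=None):
    return SearchHit(qg, qgene, sg, sgene, sim, cov, score if score is not None else sim)


class TestAllVsAll:
    def test_identical_single_proteins_reciprocal_100(self):
        prot = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQ"
        hits = all_vs_all({"A": {"a1": prot}, "B": {"b1": prot}})
        assert len(hits) == 2
        assert all(h.similarity == 100.0 and h.query_coverage == 1.0 for h in hits)

    def test_planted_orthologs_hit_near_planted_similarity(self, small_pangenome_run):
        sims = [h.similarity for h in small_pangenome_run["hits"]]
        # members are planted at ~10% mutual divergence
        assert 85.0 <= float(np.median(sims)) <= 95.0

    def test_unrelated_proteins_never_pass_5050(self):
        rng = np.random.default_rng(0)
        proteomes = {
            "A": {f"a{i}": sd.random_protein(rng) for i in range(20)},
            "B": {f"b{i}": sd.random_protein(rng) for i in range(20)},
        }
        hits = all_vs_all(proteomes)
        passing = [
            h for h in hits if h.similarity >= 50.0 and h.query_coverage >= 0.5
        ]
        assert not passing

    def test_single_proteome_rejected(self):
        with pytest.raises(ValueError):
            all_vs_all({"A": {"a1": "MKT"}})

    def test_empty_proteome_skipped_with_warning(self):
        prot = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEV"
        with pytest.warns(UserWarning):
            hits = all_vs_all({"A": {"a1": prot}, "B": {}})
        assert hits == []


class TestFindRbms:
    def test_just_below_similarity_threshold_no_edge(self):
        hits = [
            _hit("A", "a1", "B", "b1", 49.9),
            _hit("B", "b1", "A", "a1", 49.9),
        ]
        assert find_rbms(hits) == []

    def test_inclusive_boundary_at_exactly_50_50(self):
        hits = [
            _hit("A", "a1", "B", "b1", 50.0, cov=0.5),
            _hit("B", "b1", "A", "a1", 50.0, cov=0.5),
        ]
        edges = find_rbms(hits)
        assert len(edges) == 1
        assert (edges[0].gene_a, edges[0].gene_b) == ("a1", "b1")

    def test_non_reciprocal_best_gives_no_edge(self):
        # A's best is b1, but b1's best is a2
        hits = [
            _hit("A", "a1", "B", "b1", 90.0, score=90),
            _hit("B", "b1", "A", "a2", 95.0, score=95),
            _hit("B", "b1", "A", "a1", 90.0, score=90),
        ]
        assert find_rbms(hits) == []

    def test_coverage_filter_applies_per_direction(self):
        hits = [
            _hit("A", "a1", "B", "b1", 80.0, cov=0.4),  # fails its own query side
            _hit("B", "b1", "A", "a1", 80.0, cov=0.9),
        ]
        assert find_rbms(hits) == []

    def test_best_hit_tie_broken_lexicographically(self):
        hits = [
            _hit("A", "a1", "B", "b2", 80.0, score=50),
            _hit("A", "a1", "B", "b1", 80.0, score=50),
            _hit("B", "b1", "A", "a1", 80.0, score=50),
        ]
        edges = find_rbms(hits)
        assert len(edges) == 1 and edges[0].gene_b == "b1"


class TestClusterOgs:
    @staticmethod
    def _clique_edges(genomes_genes, sim=90.0):
        edges = []
        for i, (ga, a) in enumerate(genomes_genes):
            for gb, b in genomes_genes[i + 1 :]:
                edges.append(RbmEdge(ga, a, gb, b, sim, sim, sim))
        return edges

    def test_four_genome_clique_one_og(self):
        edges = self._clique_edges([("G0", "x"), ("G1", "x"), ("G2", "x"), ("G3", "x")])
        ogs = cluster_ogs(edges)
        assert len(ogs) == 1 and len(ogs[0].members) == 4

    def test_two_disjoint_cliques_two_ogs(self):
        e1 = self._clique_edges([("G0", "a"), ("G1", "a"), ("G2", "a")])
        e2 = self._clique_edges([("G0", "b"), ("G1", "b")])
        ogs = cluster_ogs(e1 + e2)
        assert sorted(len(og.members) for og in ogs) == [2, 3]

    def test_singletons_become_their_own_ogs(self):
        edges = self._clique_edges([("G0", "a"), ("G1", "a")])
        ogs = cluster_ogs(edges, all_genes=[("G0", "a"), ("G1", "a"), ("G2", "lone")])
        assert len(ogs) == 2
        assert frozenset({("G2", "lone")}) in {og.members for og in ogs}

    def test_each_gene_in_exactly_one_og(self, small_pangenome_run):
        ogs = small_pangenome_run["ogs"]
        seen = [m for og in ogs for m in og.members]
        assert len(seen) == len(set(seen))
        sim = small_pangenome_run["sim"]
        assert len(seen) == sum(len(p) for p in sim.proteomes.values())

    def test_mcl_equals_components_on_disjoint_cliques(self):
        # oracle: on clique-disjoint graphs (<=12 nodes) MCL must return
        # exactly the connected components
        rng = np.random.default_rng(1)
        for trial in range(10):
            n_cliques = int(rng.integers(1, 5))
            genes, edges = [], []
            for c in range(n_cliques):
                size = int(rng.integers(1, 4))
                members = [(f"G{c}_{i}", f"g{c}") for i in range(size)]
                genes.extend(members)
                edges.extend(self._clique_edges(members))
            got = cluster_ogs(edges, all_genes=genes, method="mcl")
            want = cluster_ogs(edges, all_genes=genes, method="components")
            assert {og.members for og in got} == {og.members for og in want}

    def test_deterministic_output(self, small_pangenome_run):
        edges = small_pangenome_run["edges"]
        sim = small_pangenome_run["sim"]
        genes = [(g, gene) for g, p in sim.proteomes.items() for gene in p]
        a = cluster_ogs(edges, all_genes=genes)
        b = cluster_ogs(edges, all_genes=genes)
        assert a == b


class TestPartition:
    @staticmethod
    def _og(i, members):
        return OrthologGroup(f"OG{i:05d}", frozenset(members))

    def test_definitions_on_three_genomes(self):
        ogs = [
            self._og(0, [("G0", "a"), ("G1", "a"), ("G2", "a")]),  # core
            self._og(1, [("G0", "b"), ("G1", "b")]),  # variable
            self._og(2, [("G2", "c")]),  # genome-specific
        ]
        part = partition_pangenome(ogs, ["G0", "G1", "G2"])
        assert (part.n_core, part.n_variable, part.n_genome_specific) == (1, 1, 1)
        assert part.n_total_ogs == 3

    def test_conservation_identity(self, small_pangenome_run):
        p = small_pangenome_run["partition"]
        assert p.n_core + p.n_variable + p.n_genome_specific == p.n_total_ogs

    def test_planted_partition_recovered_exactly(self, small_pangenome_run):
        sim = small_pangenome_run["sim"]
        p = small_pangenome_run["partition"]
        truth = sim.truth.partition_counts()
        assert (p.n_core, p.n_variable, p.n_genome_specific) == truth

    def test_presence_matrix_equals_planted_truth(self, small_pangenome_run):
        sim = small_pangenome_run["sim"]
        p = small_pangenome_run["partition"]
        # map each recovered OG to the planted OG of its members
        truth_frame = sim.truth.presence_frame()
        recovered = {}
        for og_id in p.presence.columns:
            og = next(o for o in small_pangenome_run["ogs"] if o.og_id == og_id)
            planted = {sim.gene_to_og[m] for m in og.members}
            assert len(planted) == 1  # no chimeric OGs
            recovered[og_id] = planted.pop()
        assert len(set(recovered.values())) == len(recovered)  # no split OGs
        for og_id, planted_id in recovered.items():
            assert (
                p.presence[og_id].astype(bool) == truth_frame[planted_id]
            ).all()

    def test_low_completeness_genomes_excluded(self):
        ogs = [
            self._og(0, [("G0", "a"), ("G1", "a"), ("G2", "a")]),
            self._og(1, [("G2", "b")]),
        ]
        part = partition_pangenome(
            ogs, ["G0", "G1", "G2"], completeness={"G0": 99, "G1": 98, "G2": 80}
        )
        assert part.included_genomes == ["G0", "G1"]
        assert part.n_total_ogs == 1 and part.n_core == 1

    def test_empty_og_set_rejected(self):
        with pytest.raises(ValueError):
            partition_pangenome([], ["G0"])


class TestVariableGeneClustering:
    def test_known_euclidean_distances(self):
        presence = pd.DataFrame(
            [[1, 1, 0, 0], [0, 0, 1, 1]], index=["A", "B"], columns=list("wxyz")
        )
        from scipy.spatial.distance import pdist

        assert pdist(presence.to_numpy(dtype=float))[0] == 2.0  # sqrt(4)
        tree = cluster_genomes_by_variable_genes(presence)
        assert sorted(t.name for t in tree.tips()) == ["A", "B"]

    def test_identical_rows_zero_distance_handled(self):
        presence = pd.DataFrame(
            [[1, 0], [1, 0], [0, 1]], index=["A", "B", "C"], columns=["x", "y"]
        )
        tree = cluster_genomes_by_variable_genes(presence)
        ab = tree.lca(["A", "B"])
        assert {t.name for t in ab.tips()} == {"A", "B"}

    def test_planted_two_clade_structure_recovered(self):
        rng = np.random.default_rng(2)
        left = (rng.random((3, 20)) < 0.9).astype(int)
        right = (rng.random((3, 20)) < 0.1).astype(int)
        presence = pd.DataFrame(
            np.vstack([left, right]),
            index=["L0", "L1", "L2", "R0", "R1", "R2"],
        )
        tree = cluster_genomes_by_variable_genes(presence)
        lefts = tree.lca(["L0", "L1", "L2"])
        assert {t.name for t in lefts.tips()} == {"L0", "L1", "L2"}

    def test_variable_presence_excludes_core_and_specific(self, small_pangenome_run):
        p = small_pangenome_run["partition"]
        vp = variable_presence(p)
        assert vp.shape[1] == p.n_variable


class TestCenterStarAndNj:
    def test_center_star_preserves_sequences(self):
        seqs = {"A": "MKTAYIAK", "B": "MKTGYIAK", "C": "MKTAYIK"}
        aligned = center_star_align(seqs)
        widths = {len(s) for s in aligned.values()}
        assert len(widths) == 1
        for name, seq in seqs.items():
            assert aligned[name].replace("-", "") == seq

    def test_two_genome_tree_edge_length_is_p_distance(self):
        blocks = {"OG0": {"A": "MKTAYIAK", "B": "MKTGYIAK"}}  # p-dist 1/8
        tree = core_concat_nj(blocks)
        total = sum(t.length for t in tree.traverse() if t.length)
        assert total == pytest.approx(1 / 8)

    def test_four_taxon_topology_recovered(self):
        # ((A,B),(C,D)): A/B and C/D nearly identical, clades far apart
        base1 = "MKTAYIAKQRQISFVKSHFSRQ" * 4
        base2 = "GWDNNPLHMMEECCTTVVLLII" * 4
        blocks = {
            "OG0": {
                "A": base1,
                "B": base1[:-1] + "K",
                "C": base2,
                "D": base2[:-1] + "W",
            }
        }
        tree = core_concat_nj(blocks)
        ab = tree.lca(["A", "B"])
        names = {t.name for t in ab.tips()}
        assert names in ({"A", "B"}, {"C", "D"})  # unrooted: complement ok

    def test_taxon_input_order_invariant(self):
        base1 = "MKTAYIAKQRQISFVKSHFSRQ" * 3
        base2 = "GWDNNPLHMMEECCTTVVLLII" * 3
        block = {"A": base1, "B": base1[:-1] + "K", "C": base2, "D": base2[:-1] + "W"}
        t1 = core_concat_nj({"OG0": block})
        t2 = core_concat_nj({"OG0": dict(reversed(list(block.items())))})
        assert t1.compare_rfd(t2) == 0.0

    def test_incomplete_block_dropped_with_warning(self):
        blocks = {
            "OG0": {"A": "MKTA", "B": "MKTA", "C": "MKTA"},
            "OG1": {"A": "WWWW", "B": "WWWW"},  # missing C
        }
        with pytest.warns(UserWarning):
            tree = core_concat_nj(blocks)
        assert sorted(t.name for t in tree.tips()) == ["A", "B", "C"]

    def test_p_distance_ignores_gap_columns(self):
        dm = p_distance_matrix({"A": "MK-TA", "B": "MKWTT"})
        assert dm["A", "B"] == pytest.approx(1 / 4)

    def test_core_alignment_blocks_cover_all_genomes(self, small_pangenome_run):
        blocks = core_og_alignments(
            small_pangenome_run["ogs"],
            small_pangenome_run["sim"].proteomes,
            small_pangenome_run["partition"],
        )
        assert len(blocks) == small_pangenome_run["partition"].n_core
        genomes = set(small_pangenome_run["partition"].included_genomes)
        assert all(set(b) == genomes for b in blocks.values())
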