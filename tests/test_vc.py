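"""Gene-sharing viral clusters: PCs, hypergeometric scores, MCL, summaries."""

import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from oracles import hypergeom_tail_enumeration, modularity_best_bipartition
from peatvirome import vc
from peatvirome.formats import SeqRecord
from peatvirome.vc import (
    ClusteringSummary,
    GenomeProfile,
    ViralCluster,
    annotate_habitats,
    aquatic_like_votus,
    assign_taxonomy,
    build_vc_graph,
    cluster_proteins,
    genome_profiles,
    habitat_overlap,
    mcl,
    mean_pairwise_aai,
    pair_score,
    summarize_clustering,
)


class TestProteinClustering:
    def test_identical_proteins_form_one_pc(self):
        prots = [SeqRecord(f"p{i}", "MKV" * 60) for i in range(3)]
        pcs = cluster_proteins(prots)
        assert len(pcs) == 1

    def test_unrelated_random_proteins_stay_apart(self):
        rng = np.random.default_rng(0)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        prots = [
            SeqRecord(f"p{i}", "".join(rng.choice(aa, 250))) for i in range(2)
        ]
        assert len(cluster_proteins(prots)) == 2

    def test_planted_pangenome_families_recovered(self, toy_community):
        proteins = toy_community["proteins"]
        truth = toy_community["truth"]
        pcs = cluster_proteins(proteins)
        pmap = {p: c.pc_id for c in pcs for p in c.member_ids}
        ari = adjusted_rand_score(
            [truth.protein_family[p.id] for p in proteins],
            [pmap[p.id] for p in proteins],
        )
        assert ari == 1.0


class TestPairScore:
    def test_disjoint_profiles_score_zero(self):
        a = GenomeProfile("a", frozenset({"x", "y"}))
        b = GenomeProfile("b", frozenset({"z"}))
        assert pair_score(a, b, 100, 10) == 0.0

    def test_identical_profiles_match_closed_form(self):
        pa = GenomeProfile("a", frozenset(f"pc{i}" for i in range(10)))
        p = 1 / math.comb(1000, 10)  # P(X >= 10) = P(all 10 drawn)
        expected = -math.log10(p)
        assert pair_score(pa, pa, 1000, 1) == pytest.approx(expected, rel=1e-9)

    def test_single_shared_pc_in_small_universe_scores_zero(self):
        pa = GenomeProfile("a", frozenset(f"a{i}" for i in range(9)) | {"s"})
        pb = GenomeProfile("b", frozenset(f"b{i}" for i in range(9)) | {"s"})
        assert pair_score(pa, pb, 20, 1) == pytest.approx(0.0, abs=1e-4)

    @pytest.mark.parametrize(
        "M, na, nb, c", [(16, 6, 6, 2), (16, 6, 6, 5), (12, 4, 7, 3), (10, 5, 5, 1)]
    )
    def test_tail_matches_exhaustive_enumeration(self, M, na, nb, c):
        """The hypergeometric upper tail equals exact enumeration of every
        possible draw in small universes."""
        from scipy.stats import hypergeom

        exact = hypergeom_tail_enumeration(M, na, nb, c)
        assert float(hypergeom.sf(c - 1, M, na, nb)) == pytest.approx(
            float(exact), rel=1e-12
        )


class TestMcl:
    def _clique_pair(self, eps=0.05):
        g = nx.Graph()
        for base in (0, 4):
            for i in range(4):
                for j in range(i + 1, 4):
                    g.add_edge(base + i, base + j, weight=1.0)
        g.add_edge(0, 4, weight=eps)
        return g

    def test_two_cliques_with_weak_bridge_split(self):
        g = self._clique_pair()
        vcs = mcl(g)
        parts = {frozenset(v.member_ids) for v in vcs}
        assert parts == {frozenset(range(4)), frozenset(range(4, 8))}

    def test_split_matches_exhaustive_modularity_bipartition(self):
        g = self._clique_pair()
        adj = nx.to_numpy_array(g, nodelist=range(8))
        best = modularity_best_bipartition(adj)
        vcs = mcl(g)
        assert {frozenset(v.member_ids) for v in vcs} == best

    def test_edgeless_graph_gives_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abcd")
        vcs = mcl(g)
        assert sorted(v.member_ids for v in vcs) == [["a"], ["b"], ["c"], ["d"]]

    def test_single_clique_single_cluster(self):
        g = nx.complete_graph(5)
        assert len(mcl(g)) == 1

    def test_disconnected_components_equal_per_component_runs(self):
        rng = np.random.default_rng(4)
        g = nx.Graph()
        # two random components with distinct node labels
        for offset in (0, 10):
            nodes = list(range(offset, offset + 6))
            g.add_nodes_from(nodes)
            for i in nodes:
                for j in nodes:
                    if i < j and rng.random() < 0.5:
                        g.add_edge(i, j, weight=float(rng.uniform(0.5, 2.0)))
        whole = {frozenset(v.member_ids) for v in mcl(g)}
        per_comp = set()
        for comp in nx.connected_components(g):
            sub = g.subgraph(comp).copy()
            per_comp |= {frozenset(v.member_ids) for v in mcl(sub)}
        assert whole == per_comp


class TestTaxonomyAndHabitat:
    def _vcs(self):
        return [
            ViralCluster("VC0", ["v1", "v2", "ref1"]),
            ViralCluster("VC1", ["v3"]),
            ViralCluster("VC2", ["v4", "ref2", "ref3"]),
        ]

    def test_taxonomy_transfer_and_conflicts(self):
        vcs = assign_taxonomy(
            self._vcs(),
            {"ref1": "Myoviridae", "ref2": "Podoviridae", "ref3": "Siphoviridae"},
        )
        assert vcs[0].taxonomy == "Myoviridae"
        assert vcs[1].taxonomy is None  # no reference member: unclassified
        assert vcs[2].taxonomy == "ambiguous"

    def test_habitat_union_and_aquatic_like(self):
        vcs = self._vcs()
        annotate_habitats(
            vcs,
            {"v1": "peat", "v2": "marine", "ref1": "soil", "v3": "soil", "v4": "peat",
             "ref2": "peat", "ref3": "soil"},
        )
        assert vcs[0].habitat_set == {"peat", "marine", "soil"}
        aq = aquatic_like_votus(vcs)
        assert aq == {"v1", "v2", "ref1"}

    def test_habitat_overlap_partition(self):
        vcs = self._vcs()
        annotate_habitats(
            vcs,
            {"v1": "peat", "v2": "marine", "ref1": "soil", "v3": "soil", "v4": "peat",
             "ref2": "peat", "ref3": "soil"},
        )
        ov = habitat_overlap(vcs)
        assert sum(ov.combination_counts.values()) == len(vcs)
        assert ov.n_soil_vcs == 3 and ov.n_soil_shared_aquatic == 1
        assert ov.pct_soil_shared_aquatic == pytest.approx(100 / 3)

    def test_empty_vc_set(self):
        ov = habitat_overlap([])
        assert ov.combination_counts == {} and ov.pct_soil_shared_aquatic == 0.0

    def test_merging_habitat_inputs_never_shrinks_sets(self):
        vcs = [ViralCluster("VC0", ["a", "b"])]
        annotate_habitats(vcs, {"a": "soil"})
        first = set(vcs[0].habitat_set)
        annotate_habitats(vcs, {"a": "soil", "b": "marine"})
        assert first <= vcs[0].habitat_set


class TestSummaries:
    def test_single_votu_is_one_singleton_vc(self):
        s = ClusteringSummary.from_counts(1, 1, 0)
        assert s.n_singleton_vcs == 1
        assert s.pct_singleton_vcs == 100 and s.pct_votus_in_singletons == 100

    def test_summary_identities_on_random_partitions(self):
        """Property: on arbitrary random partitions the summary identities
        hold (n_vcs = multi + singletons; votus_in_multi = n - singletons)."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(1, 60))
            labels = rng.integers(0, max(1, n // 2), n)
            votus = [f"v{i}" for i in range(n)]
            clusters = {}
            for v, l in zip(votus, labels):
                clusters.setdefault(int(l), []).append(v)
            vcs = [ViralCluster(f"VC{k}", m) for k, m in clusters.items()]
            s = summarize_clustering(votus, vcs)
            assert s.n_vcs == s.n_multi_vcs + s.n_singleton_vcs
            assert s.votus_in_multi == s.n_votus - s.n_singleton_vcs
            assert 0 <= s.pct_singleton_vcs <= 100


class TestGenusRecovery:
    def test_planted_genera_recovered(self, toy_community):
        """The full PC -> profile -> hypergeometric graph -> MCL chain
        recovers the planted genus partition on vOTU representatives."""
        truth = toy_community["truth"]
        gmap = toy_community["genome_map"]
        rep_ids = set(truth.species_rep.values())
        rep_map = gmap[gmap["genome_id"].isin(rep_ids)]
        keep = set(rep_map["protein_id"])
        pcs = cluster_proteins([p for p in toy_community["proteins"] if p.id in keep])
        profiles = genome_profiles(pcs, rep_map)
        graph = build_vc_graph(profiles)
        vcs = mcl(graph)
        cm = {m: x.vc_id for x in vcs for m in x.member_ids}
        reps = sorted(rep_ids)
        ari = adjusted_rand_score(
            [truth.species_genus[truth.contig_species[r]] for r in reps],
            [cm[r] for r in reps],
        )
        assert ari >= 0.9


class TestAai:
    def test_identical_genomes_have_aai_one(self):
        prots = {"g1": [SeqRecord("a", "MKVLW" * 50)], "g2": [SeqRecord("b", "MKVLW" * 50)]}
        vc_ = ViralCluster("VC0", ["g1", "g2"])
        assert mean_pairwise_aai(vc_, prots) == pytest.approx(1.0)

    def test_singleton_vc_undefined(self):
        assert mean_pairwise_aai(ViralCluster("VC0", ["g1"]), {"g1": []}) is None

    def test_planted_divergence_within_tolerance(self, toy_community):
        """Within a planted genus, AAI matches the substitution-model
        expectation to +/-0.02 (two species mutated independently at rate
        m from each family founder; a site differs unless both copies
        agree, including the 1/19 chance of coinciding substitutions)."""
        truth = toy_community["truth"]
        cfg = toy_community["config"]
        gmap = toy_community["genome_map"]
        prot_by_genome = {}
        by_id = {p.id: p for p in toy_community["proteins"]}
        for pid, gid in zip(gmap["protein_id"], gmap["genome_id"]):
            prot_by_genome.setdefault(gid, []).append(by_id[pid])
        genus = "g000"
        reps = [
            truth.species_rep[sp]
            for sp, g in truth.species_genus.items()
            if g == genus
        ]
        vc_ = ViralCluster("VC0", reps)
        m = cfg.protein_divergence
        expected = 1 - (2 * m * (1 - m) + m * m * (18 / 19))
        aai = mean_pairwise_aai(vc_, prot_by_genome)
        assert aai == pytest.approx(expected, abs=0.02)
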