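import numpy as np
import pytest

from ecotree.knowledge_graph import (
    Entity,
    KGError,
    KnowledgeGraph,
    complete_graph,
    gcn_embed,
    level_subgraphs,
    load_triples,
    save_triples,
    train_transe,
    transe_score,
)
from ecotree.synthetic_data import generate_kg, generate_taxonomy


def small_graph() -> KnowledgeGraph:
    g = KnowledgeGraph()
    g.add_triple("aphid", "predation", "ladybird")
    g.add_triple("aphid", "competition", "planthopper")
    g.add_triple("planthopper", "predation", "spider")
    return g


class TestLoadTriples:
    def test_three_line_file(self, tmp_path):
        path = tmp_path / "kg.tsv"
        path.write_text(
            "aphid\tpredation\tladybird\n"
            "aphid\tcompetition\tplanthopper\n"
            "planthopper\tpredation\tspider\t0.8\n"
        )
        g = load_triples(path)
        assert g.n_triples == 3
        assert g.triples[("planthopper", "predation", "spider")] == 0.8

    def test_undeclared_relation_rejected(self, tmp_path):
        path = tmp_path / "kg.tsv"
        path.write_text("aphid\tparasitism\tladybird\n")
        with pytest.raises(KGError, match="parasitism"):
            load_triples(path)

    def test_header_declared_relation_accepted(self, tmp_path):
        path = tmp_path / "kg.tsv"
        path.write_text("# relations: parasitism\naphid\tparasitism\twasp\n")
        g = load_triples(path)
        assert ("aphid", "parasitism", "wasp") in g.triples

    def test_duplicate_keeps_max_confidence(self, tmp_path):
        path = tmp_path / "kg.tsv"
        path.write_text(
            "aphid\tpredation\tladybird\t0.4\naphid\tpredation\tladybird\t0.9\n"
        )
        g = load_triples(path)
        assert g.n_triples == 1
        assert g.triples[("aphid", "predation", "ladybird")] == 0.9

    def test_confidence_outside_unit_interval_rejected(self, tmp_path):
        path = tmp_path / "kg.tsv"
        path.write_text("aphid\tpredation\tladybird\t1.5\n")
        with pytest.raises(KGError, match="confidence"):
            load_triples(path)

    def test_round_trip(self, tmp_path):
        g = small_graph()
        save_triples(g, tmp_path / "out.tsv")
        g2 = load_triples(tmp_path / "out.tsv")
        assert g2.triples == g.triples


class TestGcnEmbed:
    def test_empty_graph_empty_embedding(self):
        emb = gcn_embed(KnowledgeGraph(), d_k=8, seed=0)
        assert emb.entity_vectors == {}
        assert len(emb.relation_vectors) > 0

    def test_no_edges_no_mixing(self):
        """Isolated nodes keep transformed initial features, independent of
        the other nodes present."""
        g1 = KnowledgeGraph()
        g1.add_entity(Entity("a", "a"))
        g2 = KnowledgeGraph()
        g2.add_entity(Entity("a", "a"))
        g2.add_entity(Entity("b", "b"))
        e1 = gcn_embed(g1, d_k=16, n_layers=1, seed=0)
        e2 = gcn_embed(g2, d_k=16, n_layers=1, seed=0)
        np.testing.assert_allclose(e1.entity_vectors["a"], e2.entity_vectors["a"])

    def test_uniform_dimension_and_finite(self):
        emb = gcn_embed(small_graph(), d_k=12, seed=1)
        dims = {v.shape for v in emb.entity_vectors.values()}
        dims |= {v.shape for v in emb.relation_vectors.values()}
        assert dims == {(12,)}

    def test_enumeration_order_irrelevant(self):
        """Inserting triples in a different order leaves embeddings unchanged."""
        g1 = small_graph()
        g2 = KnowledgeGraph()
        g2.add_triple("planthopper", "predation", "spider")
        g2.add_triple("aphid", "competition", "planthopper")
        g2.add_triple("aphid", "predation", "ladybird")
        e1 = gcn_embed(g1, d_k=8, seed=3)
        e2 = gcn_embed(g2, d_k=8, seed=3)
        for eid in e1.entity_vectors:
            np.testing.assert_allclose(e1.entity_vectors[eid], e2.entity_vectors[eid])

    def test_dense_propagation_oracle(self):
        """Two-loop neighbor-sum propagation reproduces gcn_embed to 1e-6."""
        g = small_graph()
        g.add_triple("spider", "cohabitation", "ladybird")
        d_k, n_layers, seed = 6, 2, 5
        emb = gcn_embed(g, d_k=d_k, n_layers=n_layers, seed=seed)

        ids = sorted(g.entities)
        rels = sorted(g.relations)
        index = {e: i for i, e in enumerate(ids)}
        n = len(ids)
        adj = np.eye(n)
        inc = np.zeros((n, len(rels)))
        for (h, r, t), _c in g.triples.items():
            i, j = index[h], index[t]
            adj[i, j] = adj[j, i] = 1.0
            inc[i, rels.index(r)] += 1
            inc[j, rels.index(r)] += 1
        import zlib

        feats = np.empty((n, d_k + len(rels)))
        for eid, i in index.items():
            key = zlib.crc32(eid.encode()) & 0x7FFFFFFF
            feats[i, :d_k] = np.random.default_rng([seed, key]).normal(size=d_k)
        feats[:, d_k:] = inc
        deg = adj.sum(1)
        h = feats
        d_in = h.shape[1]
        wrng = np.random.default_rng([seed, 1])
        for _layer in range(n_layers):
            W = wrng.normal(scale=1.0 / np.sqrt(d_in), size=(d_in, d_k))
            agg = np.zeros_like(h)
            for i in range(n):  # explicit two-loop aggregation
                for j in range(n):
                    if adj[i, j]:
                        agg[i] += h[j] / np.sqrt(deg[i] * deg[j])
            h = np.tanh(agg @ W)
            d_in = d_k
        for eid in ids:
            np.testing.assert_allclose(
                emb.entity_vectors[eid], h[index[eid]], atol=1e-6
            )


class TestLevelSubgraphs:
    def test_grouping_under_orders(self):
        tree = generate_taxonomy(2, 1, 3, seed=0)
        graph = generate_kg(tree, predation_density=0.5, seed=0)
        emb = gcn_embed(graph, d_k=8, seed=0)
        subs = level_subgraphs(graph, tree, emb)
        assert [s.level for s in subs] == [1, 2, 3]
        assert set(subs[0].groups) == set(tree.roots)
        assert len(subs[0].embedding_view) == 2

    def test_unlinked_entity_excluded(self):
        g = small_graph()  # entities have no taxonomy links
        tree = generate_taxonomy(2, 1, 3, seed=0)
        emb = gcn_embed(g, d_k=4, seed=0)
        subs = level_subgraphs(g, tree, emb)
        assert all(not s.members for s in subs)

    def test_level3_union_covers_species_entities(self):
        tree = generate_taxonomy(2, 2, 2, seed=1)
        graph = generate_kg(tree, predation_density=0.3, seed=1)
        emb = gcn_embed(graph, d_k=8, seed=1)
        subs = level_subgraphs(graph, tree, emb)
        species_entities = {
            eid for eid, ent in graph.entities.items()
            if ent.taxon in tree and tree.node(ent.taxon).rank == "species"
        }
        assert subs[2].members == species_entities


class TestCompleteGraph:
    def test_threshold_one_adds_nothing(self):
        g = small_graph()
        out = complete_graph(g, d_k=8, epochs=5, threshold=1.0, seed=0)
        assert out.triples == g.triples

    def test_add_then_prune_round_trip(self):
        g = small_graph()
        # floor above every possible completed confidence: everything added
        # is pruned again, asserted triples survive
        out = complete_graph(g, d_k=8, epochs=5, threshold=0.0, prune_floor=1.0, seed=0)
        assert out.triples == g.triples

    def test_asserted_triples_never_removed(self):
        g = small_graph()
        out = complete_graph(g, d_k=8, epochs=20, threshold=0.8, prune_floor=0.9, seed=0)
        for key, conf in g.triples.items():
            assert out.triples[key] == conf

    def test_empty_graph_rejected(self):
        with pytest.raises(KGError):
            complete_graph(KnowledgeGraph(), seed=0)

    def test_completed_confidences_below_one(self):
        g = small_graph()
        out = complete_graph(g, d_k=8, epochs=30, threshold=0.6, prune_floor=0.0, seed=0)
        for key, conf in out.triples.items():
            if key not in g.triples:
                assert 0.6 <= conf < 1.0


class TestTransE:
    def test_planted_pattern_ranks_held_out_triples(self):
        """Food-chain motifs repeated across entity families: held-out links
        rank far above the random-guess baseline."""
        g = KnowledgeGraph()
        held_out = []
        for i in range(20):
            a, b, c = f"crop{i}", f"pest{i}", f"enemy{i}"
            g.add_triple(b, "predation", a)  # pest eats crop
            g.add_triple(b, "cohabitation", c)
            if i < 15:
                g.add_triple(c, "predation", b)  # enemy eats pest
            else:
                held_out.append((f"enemy{i}", "predation", f"pest{i}"))
        ent, rel = train_transe(g, d_k=16, epochs=150, seed=0)
        ents = sorted(g.entities)
        ranks = []
        for (h, r, t) in held_out:
            score_true = transe_score(ent, rel, h, r, t)
            scores = [transe_score(ent, rel, h, r, other) for other in ents if other != h]
            rank = 1 + sum(s > score_true for s in scores)
            ranks.append(rank)
        n_candidates = len(ents) - 1
        assert np.mean(ranks) < (n_candidates + 1) / 2  # above chance
        mrr = np.mean([1.0 / r for r in ranks])
        chance_mrr = np.mean([1.0 / k for k in range(1, n_candidates + 1)])
        assert mrr > chance_mrr
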