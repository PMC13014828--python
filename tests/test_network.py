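"""Cross-feeding graphs against brute-force oracles; edge soundness."""

import numpy as np
import pytest

from modmet.network import (
    DEFAULT_PUBLIC_GOODS,
    audit_edges,
    build_network,
    consumers_of,
    edge_table,
    module_composition,
    producers_of,
    reciprocal_pairs,
)
from modmet.presence import build_presence_matrix

from conftest import random_ko_sets


# ---------------------------------------------------------------------------
# Brute-force oracles: independent triple scans over (genome, module, compound)
# ---------------------------------------------------------------------------

def brute_producers(compound, presence, catalog):
    out = set()
    for gid in presence.index:
        for mod in catalog.modules:
            if mod.is_transporter:
                continue
            if compound in mod.products and presence.loc[gid, mod.module_id]:
                out.add(str(gid))
    return out


def brute_consumers(compound, presence, catalog):
    out = set()
    for gid in presence.index:
        for mod in catalog.modules:
            if not presence.loc[gid, mod.module_id]:
                continue
            if mod.is_transporter:
                if compound in mod.substrates and mod.direction in ("import",
                                                                    "bidirectional"):
                    out.add(str(gid))
            elif compound in mod.substrates:
                out.add(str(gid))
    return out


def brute_edge_set(membership, presence, catalog, compounds, diffusive=("formate",)):
    """Expected (src, dst, edge_type, compound, module) tuples."""
    edges = set()
    for gid in membership:
        for mod in catalog.modules:
            if not presence.loc[gid, mod.module_id]:
                continue
            if mod.is_transporter:
                for c in mod.substrates:
                    if c not in compounds:
                        continue
                    if mod.direction in ("import", "bidirectional"):
                        edges.add((c, gid, "import", c, mod.module_id))
                    if mod.direction in ("export", "bidirectional"):
                        edges.add((gid, c, "export", c, mod.module_id))
            else:
                for c in mod.products:
                    if c in compounds:
                        edges.add((gid, c, "produce", c, mod.module_id))
                        if c in diffusive:
                            edges.add((gid, c, "export", c, mod.module_id))
                for c in mod.substrates:
                    if c in compounds:
                        edges.add((c, gid, "consume", c, mod.module_id))
    return edges


def brute_reciprocal_pair_set(graph):
    """Unordered genome pairs with valid two-way exchange, enumerated from
    the edge list without any indexing shortcuts."""
    gives, takes = {}, {}
    for u, v, d in graph.edges(data=True):
        if d["edge_type"] in ("produce", "export"):
            gives.setdefault((u, d["compound"]), set()).add(d["module_id"])
        if d["edge_type"] in ("consume", "import"):
            takes.setdefault((v, d["compound"]), set()).add(d["module_id"])
    genomes = sorted({n for n, data in graph.nodes(data=True)
                      if data.get("kind") == "genome"})
    pairs = set()
    for a in genomes:
        for b in genomes:
            if a >= b:
                continue
            for c1 in DEFAULT_PUBLIC_GOODS:
                if (a, c1) not in gives or (b, c1) not in takes:
                    continue
                for c2 in DEFAULT_PUBLIC_GOODS:
                    if (b, c2) not in gives or (a, c2) not in takes:
                        continue
                    if c1 == c2 and gives[(a, c1)] == gives[(b, c2)]:
                        continue
                    pairs.add((a, b))
    return pairs


@pytest.fixture
def random_presence(full_catalog):
    rng = np.random.default_rng(77)
    ko_sets = random_ko_sets(full_catalog, 30, rng, hit_prob=0.25)
    return build_presence_matrix(sorted(ko_sets.items()), full_catalog)


class TestProducersConsumers:
    def test_pat_ack_makes_acetate_producer(self, mini_catalog):
        mat = build_presence_matrix(
            [("f", {"K00625", "K00925"})], mini_catalog
        )
        assert producers_of("acetate", mat, mini_catalog) == {"f"}

    def test_malate_consumption_via_promiscuous_transporter(self, full_catalog):
        mat = build_presence_matrix([("t", {"K11103"})], full_catalog)
        assert "t" in consumers_of("malate", mat, full_catalog)

    def test_lactate_consumption_via_utilization_complex(self, full_catalog):
        mat = build_presence_matrix(
            [("l", {"K18928", "K18929", "K18930"})], full_catalog
        )
        assert "l" in consumers_of("lactate", mat, full_catalog)

    def test_empty_matrix_gives_empty_sets(self, full_catalog):
        mat = build_presence_matrix([], full_catalog)
        assert producers_of("acetate", mat, full_catalog) == set()
        assert consumers_of("acetate", mat, full_catalog) == set()

    def test_export_only_transporter_is_not_producer(self, full_catalog):
        p63 = full_catalog["P63"]
        kos = {sorted(g.members)[0] for g in p63.requirement}
        mat = build_presence_matrix([("e", kos)], full_catalog)
        assert "e" not in producers_of("fatty-acid", mat, full_catalog)
        assert "e" not in consumers_of("fatty-acid", mat, full_catalog)

    def test_unknown_compound_rejected(self, full_catalog):
        mat = build_presence_matrix([], full_catalog)
        with pytest.raises(KeyError):
            producers_of("caviar", mat, full_catalog)

    def test_matches_brute_force_on_random_fixture(self, full_catalog,
                                                   random_presence):
        for compound in DEFAULT_PUBLIC_GOODS:
            assert producers_of(compound, random_presence, full_catalog) == \
                brute_producers(compound, random_presence, full_catalog)
            assert consumers_of(compound, random_presence, full_catalog) == \
                brute_consumers(compound, random_presence, full_catalog)


class TestBuildNetwork:
    def test_producer_consumer_path(self, mini_catalog):
        mat = build_presence_matrix(
            [("prod", {"K00625", "K00925"}), ("cons", {"K06212"})], mini_catalog
        )
        g = build_network("BH", ["prod", "cons"], mat, mini_catalog)
        types = {(u, v, d["edge_type"]) for u, v, d in g.edges(data=True)}
        assert ("prod", "acetate", "produce") in types
        assert ("acetate", "cons", "import") in types

    def test_empty_membership_gives_empty_graph(self, mini_catalog):
        mat = build_presence_matrix([("x", {"K00625"})], mini_catalog)
        g = build_network("BH", [], mat, mini_catalog)
        assert g.number_of_edges() == 0

    def test_no_acl_in_borehole_means_no_citrate_consumption(self, full_catalog):
        # members lack P40 (and any citrate route): no consume edge for citrate
        mat = build_presence_matrix(
            [("a", {"K00625", "K00925"}), ("b", {"K06212"})], full_catalog
        )
        g = build_network("BH", ["a", "b"], mat, full_catalog)
        citrate_uptake = [e for e in g.edges(data=True)
                          if e[2]["compound"] == "citrate"
                          and e[2]["edge_type"] in ("consume", "import")]
        assert citrate_uptake == []

    def test_formate_diffusive_export_without_transporter(self, full_catalog):
        p1 = full_catalog["P1"]
        kos = {sorted(g.members)[0] for g in p1.requirement}
        mat = build_presence_matrix([("f", kos)], full_catalog)
        g = build_network("BH", ["f"], mat, full_catalog)
        diffusion = [d for _, _, d in g.edges(data=True)
                     if d["edge_type"] == "export" and d["compound"] == "formate"]
        assert diffusion and all(d["mechanism"] == "diffusion" for d in diffusion)

    def test_graph_equals_brute_force_triple_scan(self, full_catalog,
                                                  random_presence):
        membership = [str(g) for g in random_presence.index]
        g = build_network("BH", membership, random_presence, full_catalog)
        got = {(u, v, d["edge_type"], d["compound"], d["module_id"])
               for u, v, d in g.edges(data=True)}
        assert got == brute_edge_set(membership, random_presence, full_catalog,
                                     set(DEFAULT_PUBLIC_GOODS))

    def test_membership_restriction_and_monotonicity(self, full_catalog,
                                                     random_presence):
        members = [str(g) for g in random_presence.index[:10]]
        g_small = build_network("BH", members, random_presence, full_catalog)
        genome_nodes = {n for n, d in g_small.nodes(data=True)
                        if d.get("kind") == "genome"}
        assert genome_nodes <= set(members)
        g_big = build_network("BH", members + [str(random_presence.index[10])],
                              random_presence, full_catalog)
        small_edges = {(u, v, d["edge_type"], d["compound"], d["module_id"])
                       for u, v, d in g_small.edges(data=True)}
        big_edges = {(u, v, d["edge_type"], d["compound"], d["module_id"])
                     for u, v, d in g_big.edges(data=True)}
        assert small_edges <= big_edges

    def test_every_edge_passes_soundness_audit(self, full_catalog,
                                               random_presence):
        membership = [str(g) for g in random_presence.index]
        g = build_network("BH", membership, random_presence, full_catalog)
        assert audit_edges(g, random_presence, full_catalog) == []

    def test_edge_table_deterministic_and_flagged_genomic_potential(
            self, full_catalog, random_presence):
        membership = [str(g) for g in random_presence.index]
        g = build_network("BH", membership, random_presence, full_catalog)
        t1, t2 = edge_table(g), edge_table(g)
        assert t1.equals(t2)
        assert (t1["evidence"] == "genomic_potential").all()


class TestReciprocalPairs:
    def test_lactate_acetate_loop(self, mini_catalog):
        # fermenter: makes lactate (P12) and takes up acetate (FocA, P60)
        # producer: uses lactate (P15) and makes acetate (P18+P19)
        mat = build_presence_matrix(
            [
                ("ferm", {"K03778", "K06212"}),
                ("prod", {"K18928", "K18929", "K18930", "K00625", "K00925"}),
            ],
            mini_catalog,
        )
        g = build_network("BH", ["ferm", "prod"], mat, mini_catalog)
        pairs = reciprocal_pairs(g)
        assert len(pairs) == 1
        (p,) = pairs
        assert {p.genome_a, p.genome_b} == {"ferm", "prod"}
        assert {p.compound_ab, p.compound_ba} == {"lactate", "acetate"}

    def test_producers_only_graph_has_no_pairs(self, mini_catalog):
        mat = build_presence_matrix(
            [("p1", {"K00625", "K00925"}), ("p2", {"K00625", "K00925"})],
            mini_catalog,
        )
        g = build_network("BH", ["p1", "p2"], mat, mini_catalog)
        # both produce acetate but neither takes anything up
        assert reciprocal_pairs(g) == []

    def test_matches_brute_force_pair_enumeration(self, full_catalog,
                                                  random_presence):
        membership = [str(g) for g in random_presence.index]
        g = build_network("BH", membership, random_presence, full_catalog)
        got = {(p.genome_a, p.genome_b) for p in reciprocal_pairs(g)}
        assert got == brute_reciprocal_pair_set(g)


class TestModuleComposition:
    def test_no_carriers_empty_mapping(self, mini_catalog):
        mat = build_presence_matrix([("x", set())], mini_catalog)
        assert module_composition("PN6", ["x"], mat, {"x": "Patescibacteria"}) == {}

    def test_single_phylum_full_fraction(self, mini_catalog):
        mat = build_presence_matrix(
            [("a", {"K02586", "K02588", "K02591"}),
             ("b", {"K02586", "K02588", "K02591"})],
            mini_catalog,
        )
        comp = module_composition("PN6", ["a", "b"], mat,
                                  {"a": "Omnitrophota", "b": "Omnitrophota"})
        assert comp == {"Omnitrophota": 2}

    def test_mixed_fixture_matches_hand_count(self, full_catalog,
                                              random_presence):
        taxonomy = {str(g): ("PhylumA" if i % 3 else "PhylumB")
                    for i, g in enumerate(random_presence.index)}
        membership = [str(g) for g in random_presence.index]
        for mid in ("P18", "P40", "PN6"):
            comp = module_composition(mid, membership, random_presence, taxonomy)
            hand = {}
            for gid in membership:
                if random_presence.loc[gid, mid]:
                    hand[taxonomy[gid]] = hand.get(taxonomy[gid], 0) + 1
            assert comp == hand
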