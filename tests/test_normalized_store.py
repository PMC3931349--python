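"""Entity graph construction, NDC attachment, queries and sqlite export."""

import sqlite3

import pytest

from dronbuild.chebi_mapper import load_role_map
from dronbuild.normalized_store import (
    EntityGraph,
    Cd,
    Cdf,
    GraphInvariantError,
    Ingredient,
    PackagedProduct,
    attach_ndcs,
    build_entities,
    export_db,
    init_provenance_tables,
    load_graph,
    query_ndcs_by_disposition,
    query_ndcs_by_ingredient,
    validate_graph,
)
from dronbuild.provenance import ProvenanceTable, compact_closure
from dronbuild.rrf_io import Atom, ReleaseVersion


def table_for(entries=None, orphaned=(), current=()):
    t = ProvenanceTable(entries=dict(entries or {}), orphaned=set(orphaned),
                        observed_current=set(current))
    return compact_closure(t)


class TestBuildEntities:
    def test_direct_translation_of_atoms_and_relationships(self):
        t = table_for(current={"1", "2", "3"})
        atoms = [(Atom("1", "IN", "ing"), 1), (Atom("2", "SCDF", "form"), 1),
                 (Atom("3", "SCD", "drug"), 1)]
        rels = [(("2", "has_ingredient", "1"), 1), (("3", "isa", "2"), 1)]
        g = build_entities(atoms, rels, {}, t)
        assert g.cdfs["2"].ingredients == {"1"}
        assert g.cds["3"].parent_cdf == "2"

    def test_merged_identifiers_collapse_to_one_entity(self):
        t = table_for({"10": "20"}, current={"20", "2"})
        atoms = [(Atom("10", "SCD", "old name"), 1), (Atom("20", "SCD", "new name"), 2),
                 (Atom("2", "SCDF", "form"), 2)]
        g = build_entities(atoms, [(("20", "isa", "2"), 2)], {}, t)
        assert set(g.cds) == {"20"}
        assert g.cds["20"].name == "new name"

    def test_branded_drug_reparents_through_merge(self):
        t = table_for({"10": "20"}, current={"20", "30", "2"})
        atoms = [(Atom("10", "SCD", "victim"), 1), (Atom("20", "SCD", "survivor"), 2),
                 (Atom("30", "SBD", "brand"), 2), (Atom("2", "SCDF", "form"), 2)]
        rels = [(("30", "tradename_of", "10"), 1), (("20", "isa", "2"), 2)]
        g = build_entities(atoms, rels, {}, t)
        assert g.bds["30"].parent_cd == "20"

    def test_error_atoms_create_no_entities_and_drop_edges(self):
        t = table_for({"10": "ERROR"}, current={"2"})
        atoms = [(Atom("10", "SCD", "bad"), 1), (Atom("2", "SCDF", "form"), 1)]
        g = build_entities(atoms, [(("10", "isa", "2"), 1)], {}, t)
        assert not g.cds

    def test_dangling_clinical_drug_kept(self):
        t = table_for(current={"3"})
        g = build_entities([(Atom("3", "SCD", "drug"), 1)], [], {}, t)
        assert g.cds["3"].parent_cdf is None


class TestAttachNdcs:
    def test_rows_attach_under_cd_or_bd(self, bundle):
        fx, result = bundle
        for pkg in result.graph.packaged.values():
            pool = result.graph.bds if pkg.parent_kind == "BD" else result.graph.cds
            assert pkg.parent_rxcui in pool

    def test_row_resolving_to_no_product_reported_unattachable(self):
        t = table_for(current={"1"})
        g = build_entities([(Atom("1", "IN", "ing"), 1)], [], {}, t)
        attach_ndcs(g, {("123", "1")})
        assert g.unattachable == [("123", "1")]
        assert not g.packaged

    def test_attached_count_matches_manifest(self, bundle):
        fx, result = bundle
        assert len(result.graph.packaged) == len(fx.manifest["included_pairs"])
        assert len(result.graph.unattachable) == fx.manifest["unattachable"]


class TestValidateGraph:
    def test_unknown_parent_rejected(self):
        g = EntityGraph(cds={"1": Cd("1", "x", parent_cdf="ghost")})
        with pytest.raises(GraphInvariantError, match="ghost"):
            validate_graph(g)

    def test_packaged_product_parent_must_exist(self):
        g = EntityGraph(packaged={"n": PackagedProduct("n", "ghost", "CD")})
        with pytest.raises(GraphInvariantError):
            validate_graph(g)

    def test_fixture_graph_is_valid(self, bundle):
        validate_graph(bundle[1].graph)


@pytest.fixture()
def hand_graph():
    """1 ingredient in 2 drug forms, 3 clinical drugs, 5 NDCs."""
    g = EntityGraph(
        ingredients={"i1": Ingredient("i1", "acetaminophen"),
                     "i2": Ingredient("i2", "codeine")},
        cdfs={"f1": Cdf("f1", "tablet", {"i1"}),
              "f2": Cdf("f2", "syrup", {"i1", "i2"}),
              "f3": Cdf("f3", "unrelated", set())},
        cds={"c1": Cd("c1", "tab 325", "f1"), "c2": Cd("c2", "tab 500", "f1"),
             "c3": Cd("c3", "syrup 120", "f2")},
        packaged={f"n{i}": PackagedProduct(f"n{i}", parent, "CD")
                  for i, parent in enumerate(["c1", "c1", "c2", "c3", "c3"])},
        dispositions=("analgesic disposition", "quiet disposition"),
        disposition_bearers={("analgesic disposition", "i1"),
                             ("analgesic disposition", "i2")},
    )
    validate_graph(g)
    return g


class TestQueries:
    def test_ingredient_query_counts_hand_checkable_fixture(self, hand_graph):
        assert query_ndcs_by_ingredient(hand_graph, "i1") == {"n0", "n1", "n2", "n3", "n4"}

    def test_ingredient_in_no_drug_form_yields_nothing(self, hand_graph):
        hand_graph.ingredients["i9"] = Ingredient("i9", "unused")
        assert query_ndcs_by_ingredient(hand_graph, "i9") == set()

    def test_unknown_ingredient_yields_empty_set(self, hand_graph):
        assert query_ndcs_by_ingredient(hand_graph, "nope") == set()

    def test_query_by_name_resolves_ingredient(self, hand_graph):
        assert query_ndcs_by_ingredient(hand_graph, "Acetaminophen") == \
            query_ndcs_by_ingredient(hand_graph, "i1")

    def test_combination_product_returned_for_both_ingredients(self, hand_graph):
        assert {"n3", "n4"} <= query_ndcs_by_ingredient(hand_graph, "i1")
        assert query_ndcs_by_ingredient(hand_graph, "i2") == {"n3", "n4"}

    def test_disposition_query_is_union_over_bearers(self, hand_graph):
        expected = query_ndcs_by_ingredient(hand_graph, "i1") | \
            query_ndcs_by_ingredient(hand_graph, "i2")
        assert query_ndcs_by_disposition(hand_graph, "analgesic disposition") == expected

    def test_disposition_without_bearers_yields_nothing(self, hand_graph):
        assert query_ndcs_by_disposition(hand_graph, "quiet disposition") == set()

    def test_disposition_union_property_on_fixture(self, bundle):
        _fx, result = bundle
        g = result.graph
        for disposition in g.dispositions:
            bearers = {r for d, r in g.disposition_bearers if d == disposition}
            union = set().union(*[query_ndcs_by_ingredient(g, b) for b in bearers] or [set()])
            assert query_ndcs_by_disposition(g, disposition) == union


class TestSqliteExport:
    def test_uncompacted_table_refused(self):
        conn = sqlite3.connect(":memory:")
        conn.executescript("CREATE TABLE rxnorm (ordinal INTEGER, version TEXT);"
                           "CREATE TABLE rxcui (a,b,c,d);"
                           "CREATE TABLE deprecated_rxcuis (a,b,c);")
        with pytest.raises(ValueError, match="compacted"):
            init_provenance_tables(conn, ProvenanceTable(), [])

    def test_export_and_reload_round_trips_the_graph(self, bundle, tmp_path):
        fx, result = bundle
        db = tmp_path / "store.sqlite"
        versions = [s.version for s in result.snapshots]
        export_db(db, result.graph, result.table, result.registry, versions,
                  load_role_map())
        loaded = load_graph(db)
        g = result.graph
        assert loaded.entity_counts() == g.entity_counts()
        assert set(loaded.cds) == set(g.cds)
        assert {c.rxcui: c.parent_cdf for c in loaded.cds.values()} == \
            {c.rxcui: c.parent_cdf for c in g.cds.values()}
        assert loaded.disposition_bearers == g.disposition_bearers
        for rx in list(g.ingredients)[:3]:
            assert query_ndcs_by_ingredient(loaded, rx) == query_ndcs_by_ingredient(g, rx)
        # provenance rows present: one per release plus every identifier
        conn = sqlite3.connect(db)
        assert conn.execute("SELECT COUNT(*) FROM rxnorm").fetchone()[0] == len(versions)
        n_ids = conn.execute("SELECT COUNT(*) FROM rxcui").fetchone()[0]
        assert n_ids == len(result.table.observed_current) + len(result.table.entries)
        conn.close()
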