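"""IRI minting, axiom patterns, modular routing and round-trip serialization."""

import pytest
from rdflib import OWL, RDF, RDFS, BNode, Literal, URIRef

from dronbuild.normalized_store import (
    Bd,
    Cd,
    Cdf,
    EntityGraph,
    Ingredient,
    PackagedProduct,
)
from dronbuild.chebi_mapper import IngredientMapping
from dronbuild.owl_emitter import (
    BEARER_OF,
    HAS_PROPER_PART,
    HAS_RXCUI,
    MODULE_NAMES,
    IriMinter,
    IriOverflowError,
    OntologyModule,
    OntologyModuleSet,
    emit,
    load_curated_upper,
    read_modules,
    serialize_module,
    unsatisfiable_classes,
    write_modules,
)


@pytest.fixture(scope="module")
def curated():
    return load_curated_upper()


def small_graph():
    return EntityGraph(
        ingredients={"101": Ingredient("101", "ginger extract"),
                     "102": Ingredient(
                         "102", "furosemide",
                         IngredientMapping("102", "http://purl.obolibrary.org/obo/CHEBI_47426",
                                           "CHEBI", "label"))},
        cdfs={"201": Cdf("201", "form", {"101", "102"})},
        cds={"301": Cd("301", "drug", "201")},
        bds={"401": Bd("401", "brand", "301")},
        packaged={"55555": PackagedProduct("55555", "401", "BD"),
                  "66666": PackagedProduct("66666", "301", "CD")},
        dispositions=("function-inhibiting Na-K-Cl cotransporter 2 (NKCC2) binding disposition",),
        disposition_bearers={(
            "function-inhibiting Na-K-Cl cotransporter 2 (NKCC2) binding disposition", "102")},
    )


class TestMinting:
    def test_iris_are_zero_padded_eight_digits(self):
        assert str(IriMinter(1).mint()).endswith("DRON_00000001")

    def test_counter_overflow_is_an_error(self):
        with pytest.raises(IriOverflowError):
            IriMinter(100_000_000).mint()

    def test_identical_input_yields_identical_assignment(self, curated):
        a = emit(small_graph(), curated)
        b = emit(small_graph(), curated)
        for name in MODULE_NAMES:
            assert a.modules[name].triples == b.modules[name].triples

    def test_permuted_input_order_yields_identical_assignment(self, curated):
        g1 = small_graph()
        g2 = small_graph()
        # rebuild every dict in reversed insertion order
        g2.ingredients = dict(reversed(list(g2.ingredients.items())))
        g2.packaged = dict(reversed(list(g2.packaged.items())))
        a, b = emit(g1, curated), emit(g2, curated)
        for name in MODULE_NAMES:
            assert serialize_module(a.modules[name]) == serialize_module(b.modules[name])


@pytest.fixture(scope="module")
def modules(curated):
    return emit(small_graph(), curated)


class TestAxiomPatterns:
    def find_class(self, triples, label):
        for s, p, o in triples:
            if p == RDFS.label and str(o) == label:
                return s
        raise AssertionError(f"no class labelled {label!r}")

    def existential_parents(self, triples, subject, prop):
        out = []
        for s, p, o in triples:
            if s == subject and p == RDFS.subClassOf and isinstance(o, BNode):
                props = {pp: oo for ss, pp, oo in triples if ss == o}
                if props.get(OWL.onProperty) == prop:
                    out.append(props[OWL.someValuesFrom])
        return out

    def test_clinical_drug_subclass_of_its_form(self, modules, curated):
        rx = modules.modules["dron-rxnorm"].triples
        cd = self.find_class(rx, "drug")
        cdf = self.find_class(rx, "form")
        assert (cd, RDFS.subClassOf, cdf) in rx
        assert (cdf, RDFS.subClassOf, curated.drug_product) in rx

    def test_branded_drug_subclass_of_clinical_drug(self, modules):
        rx = modules.modules["dron-rxnorm"].triples
        assert (self.find_class(rx, "brand"), RDFS.subClassOf,
                self.find_class(rx, "drug")) in rx

    def test_drug_form_has_one_part_restriction_per_ingredient(self, modules):
        rx = modules.modules["dron-rxnorm"].triples
        cdf = self.find_class(rx, "form")
        assert len(self.existential_parents(rx, cdf, HAS_PROPER_PART)) == 2

    def test_packaged_product_pattern(self, modules, curated):
        rx = modules.modules["dron-rxnorm"].triples
        pkg = self.find_class(rx, "NDC 55555")
        assert (pkg, RDFS.subClassOf, curated.packaged_drug_product) in rx
        parents = self.existential_parents(rx, pkg, HAS_PROPER_PART)
        assert parents == [self.find_class(rx, "brand")]

    def test_every_packaged_class_has_exactly_one_product_part(self, modules):
        rx = modules.modules["dron-rxnorm"].triples
        for label in ("NDC 55555", "NDC 66666"):
            pkg = self.find_class(rx, label)
            assert len(self.existential_parents(rx, pkg, HAS_PROPER_PART)) == 1

    def test_unmatched_ingredient_parented_under_processed_material(self, modules, curated):
        rx = modules.modules["dron-rxnorm"].triples
        ginger = self.find_class(rx, "ginger extract")
        assert (ginger, RDFS.subClassOf, curated.processed_material) in rx

    def test_disposition_link_asserted_as_bearer_of_restriction(self, modules, curated):
        chebi = modules.modules["dron-chebi"].triples
        ing = URIRef("http://purl.obolibrary.org/obo/CHEBI_47426")
        disposition = curated.disposition_iri(
            "function-inhibiting Na-K-Cl cotransporter 2 (NKCC2) binding disposition")
        assert self.existential_parents(chebi, ing, BEARER_OF) == [disposition]

    def test_release_derived_classes_carry_one_rxcui_annotation(self, modules):
        rx = modules.modules["dron-rxnorm"].triples
        for cls in modules.modules["dron-rxnorm"].classes():
            annotations = [o for s, p, o in rx if s == cls and p == HAS_RXCUI]
            assert len(annotations) == 1, cls

    def test_connector_module_only_imports(self, modules):
        full = modules.modules["dron-full"]
        assert not full.classes()
        imports = {o for s, p, o in full.triples if p == OWL.imports}
        assert len(imports) == 4

    def test_chain_from_drug_classes_reaches_drug_product(self, modules, curated):
        triples = modules.all_triples()
        parents = {}
        for s, p, o in triples:
            if p == RDFS.subClassOf and not isinstance(o, BNode):
                parents.setdefault(s, set()).add(o)
        rx = modules.modules["dron-rxnorm"].triples
        for label in ("form", "drug", "brand"):
            node, seen = self.find_class(rx, label), set()
            stack = [node]
            reached = False
            while stack:
                n = stack.pop()
                if n == curated.drug_product:
                    reached = True
                    break
                for parent in parents.get(n, ()):
                    if parent not in seen:
                        seen.add(parent)
                        stack.append(parent)
            assert reached, label


class TestCurated:
    def test_exactly_six_disposition_classes(self, curated):
        labelled = [c for c in curated.classes
                    if c.label.endswith("disposition") and not c.stub]
        assert len(labelled) == 6

    def test_upper_module_valid_for_empty_graph(self, curated, tmp_path):
        modules = emit(EntityGraph(), curated)
        write_modules(modules, tmp_path)
        loaded = read_modules(tmp_path)
        assert loaded.modules["dron-upper"].classes() == \
            modules.modules["dron-upper"].classes()


class TestRoundTrip:
    def test_serialize_parse_serialize_is_a_fixed_point(self, curated, tmp_path):
        modules = emit(small_graph(), curated)
        paths = write_modules(modules, tmp_path)
        loaded = read_modules(tmp_path)
        for name, path in zip(MODULE_NAMES, paths):
            assert loaded.modules[name].triples == modules.modules[name].triples
            assert serialize_module(loaded.modules[name]) == path.read_bytes()


class TestSatisfiability:
    def test_emitted_fixture_ontology_has_no_unsatisfiable_class(self, bundle):
        assert unsatisfiable_classes(bundle[1].modules) == set()

    def test_nothing_superclass_detected(self, curated):
        modules = emit(small_graph(), curated)
        rx = modules.modules["dron-rxnorm"]
        victim = next(iter(rx.classes()))
        rx.triples.add((victim, RDFS.subClassOf, OWL.Nothing))
        assert str(victim) in unsatisfiable_classes(modules)
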