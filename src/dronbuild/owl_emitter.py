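"""Serialization of the entity graph as a five-module OWL 2 artifact.

The ontology ships as five RDF/XML modules: ``dron-upper`` (the
hand-curated structural classes, the six dispositions, and the property
declarations), ``dron-chebi`` (ingredient classes reusing ChEBI IRIs plus
their imported superclass structure), ``dron-pro`` (Protein Ontology
stubs), ``dron-rxnorm`` (everything generated from the release series:
minted ingredients, drug forms, clinical and branded drugs, and one
packaged-product class per NDC), and ``dron-full``, a connector that only
imports the other four.

Generation follows six ordered steps: (1) ingredient classes, with
external IRIs where mapped and freshly minted ones (parented under
'processed material') otherwise; (2) disposition links, asserted as
existential ``bearer_of`` restrictions on the ingredient classes; (3)
drug-form classes under 'drug product' with one existential
``has_proper_part`` restriction per ingredient; (4) clinical drugs as
subclasses of their drug form; (5) branded drugs as subclasses of their
clinical drug; (6) packaged products under 'packaged drug product', each
with exactly one ``has_proper_part`` restriction on its clinical or
branded drug.  Every class derived from the release series carries one
``has_Rxcui`` annotation.

Output is deterministic: IRIs are minted in sorted entity order,
restriction blank nodes carry content-derived labels, and triples are
serialized in sorted order, so identical input yields byte-identical
files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import rdflib
from rdflib import OWL, RDF, RDFS, BNode, Literal, URIRef

from .chebi_mapper import ClosureRecord
from .normalized_store import EntityGraph, validate_graph

logger = logging.getLogger(__name__)

OBO = "http://purl.obolibrary.org/obo/"
DRON_PREFIX = OBO + "DRON_"
OBOINOWL_DEF = URIRef(OBO + "IAO_0000115")  # textual definition annotation

MODULE_NAMES = ("dron-full", "dron-chebi", "dron-rxnorm", "dron-pro", "dron-upper")

HAS_PROPER_PART = URIRef(DRON_PREFIX + "00000090")
BEARER_OF = URIRef(OBO + "RO_0000053")
HAS_RXCUI = URIRef(DRON_PREFIX + "00000099")


class IriOverflowError(RuntimeError):
    """The eight-digit minting counter is exhausted."""


@dataclass
class IriMinter:
    """Monotone counter minting ``DRON_`` IRIs with zero-padded 8-digit tails.

    Minting is performed in a fixed order (entity type, then terminal
    identifier sorted numerically, then NDC code) so that identical input
    — in any iteration order — yields an identical IRI assignment.
    """
    counter: int = 10000

    def mint(self) -> URIRef:
        if self.counter > 99_999_999:
            raise IriOverflowError("minting counter exceeds eight digits")
        iri = URIRef(f"{DRON_PREFIX}{self.counter:08d}")
        self.counter += 1
        return iri


def _numeric_key(rxcui: str) -> tuple[int, str]:
    return (len(rxcui), rxcui)  # digit strings sort numerically


# ---------------------------------------------------------------------------
# Curated upper module
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UpperClass:
    iri: str
    label: str
    parent: str | None = None
    definition: str | None = None
    stub: bool = False


@dataclass
class CuratedUpper:
    """Statically shipped upper-module content (never generated)."""
    classes: tuple[UpperClass, ...]
    object_properties: tuple[UpperClass, ...]
    annotation_properties: tuple[UpperClass, ...]

    def __post_init__(self) -> None:
        dispositions = [c for c in self.classes if c.label.endswith("disposition")
                        and not c.stub]
        if len(dispositions) != 6:
            raise ValueError(f"expected exactly six disposition classes, got {len(dispositions)}")

    def by_label(self, label: str) -> UpperClass:
        for c in self.classes:
            if c.label == label:
                return c
        raise KeyError(label)

    @property
    def drug_product(self) -> URIRef:
        return URIRef(self.by_label("drug product").iri)

    @property
    def packaged_drug_product(self) -> URIRef:
        return URIRef(self.by_label("packaged drug product").iri)

    @property
    def processed_material(self) -> URIRef:
        return URIRef(self.by_label("processed material").iri)

    def disposition_iri(self, label: str) -> URIRef:
        return URIRef(self.by_label(label).iri)


def load_curated_upper(path: str | Path | None = None) -> CuratedUpper:
    if path is not None:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    else:
        data = json.loads(
            resources.files("dronbuild.data").joinpath("upper_module.json")
            .read_text(encoding="utf-8"))

    def conv(items: list[dict]) -> tuple[UpperClass, ...]:
        return tuple(UpperClass(i["iri"], i["label"], i.get("parent"),
                                i.get("definition"), i.get("stub", False))
                     for i in items)

    return CuratedUpper(conv(data["classes"]), conv(data["object_properties"]),
                        conv(data["annotation_properties"]))


# ---------------------------------------------------------------------------
# Module set
# ---------------------------------------------------------------------------

Triple = tuple  # (s, p, o) of rdflib terms


@dataclass
class OntologyModule:
    name: str
    iri: URIRef
    triples: set[Triple] = field(default_factory=set)

    def classes(self) -> set[URIRef]:
        return {s for s, p, o in self.triples
                if p == RDF.type and o == OWL.Class and isinstance(s, URIRef)}


@dataclass
class OntologyModuleSet:
    modules: dict[str, OntologyModule]

    def __post_init__(self) -> None:
        if set(self.modules) != set(MODULE_NAMES):
            raise ValueError(f"expected modules {MODULE_NAMES}, got {sorted(self.modules)}")

    def class_counts(self) -> dict[str, int]:
        return {name: len(m.classes()) for name, m in self.modules.items()}

    def all_triples(self) -> set[Triple]:
        out: set[Triple] = set()
        for m in self.modules.values():
            out |= m.triples
        return out


def _restriction(triples: set[Triple], subject: URIRef, prop: URIRef,
                 filler: URIRef) -> None:
    """Assert SubClassOf(subject, prop some filler) with a stable blank node."""
    digest = hashlib.sha1(f"{subject}|{prop}|{filler}".encode()).hexdigest()[:16]
    b = BNode("r" + digest)
    triples.add((subject, RDFS.subClassOf, b))
    triples.add((b, RDF.type, OWL.Restriction))
    triples.add((b, OWL.onProperty, prop))
    triples.add((b, OWL.someValuesFrom, filler))


def _declare(triples: set[Triple], iri: URIRef, label: str | None = None) -> None:
    triples.add((iri, RDF.type, OWL.Class))
    if label:
        triples.add((iri, RDFS.label, Literal(label)))


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

def emit(
    graph: EntityGraph,
    curated: CuratedUpper,
    chebi_closure: list[ClosureRecord] | None = None,
    pro_stubs: list[tuple[str, str, str | None]] | None = None,
    minter: IriMinter | None = None,
) -> OntologyModuleSet:
    """Generate the five-module set from a validated entity graph.

    *chebi_closure* carries the imported ChEBI classes with their in-set
    is-a edges; *pro_stubs* are (IRI, label, parent IRI) rows for the
    Protein Ontology classes referenced by overrides.  Raises if the
    entity graph violates its structural invariants.
    """
    validate_graph(graph)
    minter = minter or IriMinter()
    chebi_closure = chebi_closure or []
    pro_stubs = pro_stubs or []

    mods = {name: OntologyModule(name, URIRef(f"{OBO}dron/{name}.owl"))
            for name in MODULE_NAMES}
    upper_t = mods["dron-upper"].triples
    chebi_t = mods["dron-chebi"].triples
    pro_t = mods["dron-pro"].triples
    rx_t = mods["dron-rxnorm"].triples

    # --- curated upper module (shipped statically) ---
    for c in curated.classes:
        _declare(upper_t, URIRef(c.iri), c.label)
        if c.parent:
            upper_t.add((URIRef(c.iri), RDFS.subClassOf, URIRef(c.parent)))
        if c.definition:
            upper_t.add((URIRef(c.iri), OBOINOWL_DEF, Literal(c.definition)))
    for p in curated.object_properties:
        upper_t.add((URIRef(p.iri), RDF.type, OWL.ObjectProperty))
        upper_t.add((URIRef(p.iri), RDFS.label, Literal(p.label)))
    for p in curated.annotation_properties:
        upper_t.add((URIRef(p.iri), RDF.type, OWL.AnnotationProperty))
        upper_t.add((URIRef(p.iri), RDFS.label, Literal(p.label)))

    # --- step 1: ingredient classes (mint in sorted order) ---
    ingredient_iri: dict[str, URIRef] = {}
    pro_labels = {iri: label for iri, label, _ in pro_stubs}
    for rxcui in sorted(graph.ingredients, key=_numeric_key):
        ing = graph.ingredients[rxcui]
        mapping = ing.mapping
        if mapping is not None and mapping.target_iri:
            ingredient_iri[rxcui] = URIRef(mapping.target_iri)
        else:
            ingredient_iri[rxcui] = minter.mint()

    chebi_class_iris = {r.iri for r in chebi_closure}
    for record in chebi_closure:
        _declare(chebi_t, URIRef(record.iri), record.label)
        for parent in record.parents:
            chebi_t.add((URIRef(record.iri), RDFS.subClassOf, URIRef(parent)))
    for iri, label, parent in pro_stubs:
        _declare(pro_t, URIRef(iri), label)
        if parent:
            pro_t.add((URIRef(iri), RDFS.subClassOf, URIRef(parent)))

    def ingredient_module(rxcui: str) -> set[Triple]:
        mapping = graph.ingredients[rxcui].mapping
        source = mapping.source if mapping is not None else "DRON"
        return {"CHEBI": chebi_t, "PRO": pro_t}.get(source, rx_t)

    for rxcui in sorted(graph.ingredients, key=_numeric_key):
        ing = graph.ingredients[rxcui]
        iri = ingredient_iri[rxcui]
        target = ingredient_module(rxcui)
        if target is rx_t:  # freshly minted: declare and parent under processed material
            _declare(rx_t, iri, ing.name)
            rx_t.add((iri, RDFS.subClassOf, curated.processed_material))
        elif str(iri) not in chebi_class_iris and str(iri) not in pro_labels:
            # mapped class not covered by the imported closure/stubs: declare here
            _declare(target, iri, ing.name)
        target.add((iri, HAS_RXCUI, Literal(rxcui)))
        if ing.orphaned:
            target.add((iri, RDFS.comment, _ORPHAN_NOTE))

    # --- step 2: disposition links via bearer_of ---
    for disposition, rxcui in sorted(graph.disposition_bearers):
        iri = ingredient_iri[rxcui]
        _restriction(ingredient_module(rxcui), iri, BEARER_OF,
                     curated.disposition_iri(disposition))

    # --- step 3: drug forms under 'drug product' with ingredient parts ---
    cdf_iri = {rxcui: minter.mint() for rxcui in sorted(graph.cdfs, key=_numeric_key)}
    for rxcui, iri in cdf_iri.items():
        cdf = graph.cdfs[rxcui]
        _declare(rx_t, iri, cdf.name)
        rx_t.add((iri, RDFS.subClassOf, curated.drug_product))
        rx_t.add((iri, HAS_RXCUI, Literal(rxcui)))
        for ing in sorted(cdf.ingredients, key=_numeric_key):
            _restriction(rx_t, iri, HAS_PROPER_PART, ingredient_iri[ing])
        if cdf.orphaned:
            rx_t.add((iri, RDFS.comment, _ORPHAN_NOTE))

    # --- step 4: clinical drugs under their drug form ---
    cd_iri = {rxcui: minter.mint() for rxcui in sorted(graph.cds, key=_numeric_key)}
    for rxcui, iri in cd_iri.items():
        cd = graph.cds[rxcui]
        _declare(rx_t, iri, cd.name)
        parent = cdf_iri[cd.parent_cdf] if cd.parent_cdf else curated.drug_product
        rx_t.add((iri, RDFS.subClassOf, parent))
        rx_t.add((iri, HAS_RXCUI, Literal(rxcui)))
        if cd.orphaned:
            rx_t.add((iri, RDFS.comment, _ORPHAN_NOTE))

    # --- step 5: branded drugs under their clinical drug ---
    bd_iri = {rxcui: minter.mint() for rxcui in sorted(graph.bds, key=_numeric_key)}
    for rxcui, iri in bd_iri.items():
        bd = graph.bds[rxcui]
        _declare(rx_t, iri, bd.name)
        parent = cd_iri[bd.parent_cd] if bd.parent_cd else curated.drug_product
        rx_t.add((iri, RDFS.subClassOf, parent))
        rx_t.add((iri, HAS_RXCUI, Literal(rxcui)))
        if bd.orphaned:
            rx_t.add((iri, RDFS.comment, _ORPHAN_NOTE))

    # --- step 6: packaged products, one per NDC ---
    for ndc in sorted(graph.packaged):
        pkg = graph.packaged[ndc]
        iri = minter.mint()
        _declare(rx_t, iri, f"NDC {ndc}")
        rx_t.add((iri, RDFS.subClassOf, curated.packaged_drug_product))
        parent = (bd_iri if pkg.parent_kind == "BD" else cd_iri)[pkg.parent_rxcui]
        _restriction(rx_t, iri, HAS_PROPER_PART, parent)
        rx_t.add((iri, HAS_RXCUI, Literal(pkg.parent_rxcui)))
        if pkg.orphaned:
            rx_t.add((iri, RDFS.comment, _ORPHAN_NOTE))

    # --- connector module ---
    full = mods["dron-full"]
    for name in MODULE_NAMES:
        if name != "dron-full":
            full.triples.add((full.iri, OWL.imports, mods[name].iri))

    return OntologyModuleSet(mods)


_ORPHAN_NOTE = Literal(
    "orphaned: the source identifier vanished from the release series "
    "with no retirement record"
)


# ---------------------------------------------------------------------------
# Serialization (deterministic RDF/XML) and round-trip loading
# ---------------------------------------------------------------------------

def serialize_module(module: OntologyModule) -> bytes:
    """Serialize one module to RDF/XML with fully deterministic bytes."""
    g = rdflib.Graph()
    g.bind("obo", OBO)
    g.bind("owl", OWL)
    g.add((module.iri, RDF.type, OWL.Ontology))
    for s, p, o in sorted(module.triples, key=lambda t: (str(t[0]), str(t[1]), str(t[2]))):
        g.add((s, p, o))
    return g.serialize(format="xml", encoding="utf-8")


def write_modules(module_set: OntologyModuleSet, out_dir: str | Path) -> list[Path]:
    """Write one ``.owl`` file per module; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in MODULE_NAMES:
        path = out_dir / f"{name}.owl"
        path.write_bytes(serialize_module(module_set.modules[name]))
        paths.append(path)
    return paths


def _canonicalize_bnodes(triples: set[Triple]) -> set[Triple]:
    """Relabel restriction blank nodes by content so parses are comparable."""
    info: dict[BNode, dict] = {}
    subjects: dict[BNode, URIRef] = {}
    for s, p, o in triples:
        if isinstance(o, BNode) and p == RDFS.subClassOf:
            subjects[o] = s
        if isinstance(s, BNode):
            info.setdefault(s, {})[p] = o
    relabel: dict[BNode, BNode] = {}
    for b, props in info.items():
        subj, prop, filler = subjects.get(b), props.get(OWL.onProperty), \
            props.get(OWL.someValuesFrom)
        if subj is None or prop is None or filler is None:
            continue
        digest = hashlib.sha1(f"{subj}|{prop}|{filler}".encode()).hexdigest()[:16]
        relabel[b] = BNode("r" + digest)

    def sub(term):
        return relabel.get(term, term) if isinstance(term, BNode) else term

    return {(sub(s), p, sub(o)) for s, p, o in triples}


def read_modules(directory: str | Path) -> OntologyModuleSet:
    """Parse a written module directory back into an in-memory module set."""
    directory = Path(directory)
    mods: dict[str, OntologyModule] = {}
    for name in MODULE_NAMES:
        g = rdflib.Graph()
        g.parse(str(directory / f"{name}.owl"))
        iri = URIRef(f"{OBO}dron/{name}.owl")
        triples = {(s, p, o) for s, p, o in g
                   if not (s == iri and p == RDF.type and o == OWL.Ontology)}
        mods[name] = OntologyModule(name, iri, _canonicalize_bnodes(triples))
    return OntologyModuleSet(mods)


# ---------------------------------------------------------------------------
# Structural satisfiability check
# ---------------------------------------------------------------------------

_ALLOWED_PREDICATES = {
    RDF.type, RDFS.subClassOf, RDFS.label, RDFS.comment, OWL.onProperty,
    OWL.someValuesFrom, OWL.imports, HAS_RXCUI, OBOINOWL_DEF,
}
_FORBIDDEN_PREDICATES = {OWL.complementOf, OWL.disjointWith}


def unsatisfiable_classes(module_set: OntologyModuleSet) -> set[str]:
    """Classes that cannot have instances, by structural analysis.

    The emitted fragment contains only atomic subsumptions and existential
    restrictions over named classes — no negation, disjointness, or
    cardinality ceilings — so a named class is unsatisfiable exactly when
    ``owl:Nothing`` is among its (transitive) superclasses.  The check
    first verifies the axioms actually stay inside that fragment (raising
    on anything it cannot analyse), then walks the subsumption graph.
    """
    triples = module_set.all_triples()
    parents: dict[URIRef, set[URIRef]] = {}
    for s, p, o in triples:
        if p in _FORBIDDEN_PREDICATES:
            raise ValueError(f"axiom outside the analysable fragment: {s} {p} {o}")
        if p not in _ALLOWED_PREDICATES:
            raise ValueError(f"unexpected predicate in emitted module: {p}")
        if p == RDFS.subClassOf and isinstance(s, URIRef) and isinstance(o, URIRef):
            parents.setdefault(s, set()).add(o)

    bad: set[str] = set()
    for cls in {s for s, p, o in triples if p == RDF.type and o == OWL.Class
                and isinstance(s, URIRef)}:
        seen, stack = set(), [cls]
        while stack:
            node = stack.pop()
            if node == OWL.Nothing:
                bad.add(str(cls))
                break
            for parent in parents.get(node, ()):
                if parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
    return bad
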