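"""Lexical mapping of drug ingredients to ChEBI classes.

Ingredient atoms are matched by exact (normalized) name against three
annotation types on ChEBI classes — ``rdfs:label``, exact synonym, and
related synonym.  An exact match is taken to mean the ingredient and the
ChEBI class name the same chemical entity, so the ChEBI IRI is reused for
the ingredient; manual overrides bypass the lexical index (the shipped
override maps somatropin to the Protein Ontology somatotropin class,
because its name lexically collides with the ChEBI *role* 'growth
hormone', which is not a molecule).  Ingredients with no match anywhere
are minted fresh IRIs downstream and parented under 'processed material'.

The matched classes' superclass structure is imported (ancestor closure
over asserted is-a), and disposition–ingredient links are mined from ChEBI
role assignments for the three dispositions that have a ChEBI-role
counterpart; the other three dispositions carry manually curated
ingredient lists.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import rdflib
from rdflib import OWL, RDF, RDFS, URIRef

from .rrf_io import Atom

logger = logging.getLogger(__name__)

OBO = "http://purl.obolibrary.org/obo/"
OBOINOWL = "http://www.geneontology.org/formats/oboInOwl#"
EXACT_SYN_IRI = URIRef(OBOINOWL + "hasExactSynonym")
RELATED_SYN_IRI = URIRef(OBOINOWL + "hasRelatedSynonym")
#: 'has role' object property linking a chemical class to its ChEBI roles.
HAS_ROLE_IRI = URIRef(OBO + "RO_0000087")

#: Annotation types in tie-break priority order (label beats synonyms).
ANNOTATION_TYPES = ("label", "exact_synonym", "related_synonym")

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Case-fold, trim and collapse internal whitespace for exact matching."""
    return _WS.sub(" ", name.strip()).casefold()


class RoleNotFoundError(KeyError):
    """A configured ChEBI role IRI is absent from the loaded snapshot."""


# ---------------------------------------------------------------------------
# Ontology snapshot
# ---------------------------------------------------------------------------

@dataclass
class ChebiSnapshot:
    """In-memory view of a ChEBI-style ontology snapshot."""
    labels: dict[str, str] = field(default_factory=dict)
    exact_synonyms: dict[str, set[str]] = field(default_factory=dict)
    related_synonyms: dict[str, set[str]] = field(default_factory=dict)
    parents: dict[str, set[str]] = field(default_factory=dict)
    roles: dict[str, set[str]] = field(default_factory=dict)
    role_form: str | None = None  # "restriction" or "annotation"

    def classes(self) -> set[str]:
        return set(self.labels) | set(self.parents)


def load_ontology(path: str | Path) -> ChebiSnapshot:
    """Load an OWL (RDF serialization) or OBO snapshot."""
    path = Path(path)
    if path.suffix.lower() == ".obo":
        return _load_obo(path)
    return _load_rdf(path)


def _load_rdf(path: Path) -> ChebiSnapshot:
    g = rdflib.Graph()
    g.parse(str(path))
    snap = ChebiSnapshot()
    for cls in g.subjects(RDF.type, OWL.Class):
        if not isinstance(cls, URIRef):
            continue
        iri = str(cls)
        label = g.value(cls, RDFS.label)
        if label is not None:
            snap.labels[iri] = str(label)
        else:
            snap.labels.setdefault(iri, "")
        for syn in g.objects(cls, EXACT_SYN_IRI):
            snap.exact_synonyms.setdefault(iri, set()).add(str(syn))
        for syn in g.objects(cls, RELATED_SYN_IRI):
            snap.related_synonyms.setdefault(iri, set()).add(str(syn))
        for parent in g.objects(cls, RDFS.subClassOf):
            if isinstance(parent, URIRef):
                snap.parents.setdefault(iri, set()).add(str(parent))

    # Role linkage: existential has-role restrictions first, then plain
    # has-role triples (annotation form); log which shape was found.
    restriction_links = 0
    for cls in g.subjects(RDF.type, OWL.Class):
        if not isinstance(cls, URIRef):
            continue
        for parent in g.objects(cls, RDFS.subClassOf):
            if isinstance(parent, URIRef):
                continue
            if g.value(parent, OWL.onProperty) == HAS_ROLE_IRI:
                filler = g.value(parent, OWL.someValuesFrom)
                if isinstance(filler, URIRef):
                    snap.roles.setdefault(str(cls), set()).add(str(filler))
                    restriction_links += 1
    if restriction_links:
        snap.role_form = "restriction"
    else:
        for s, o in g.subject_objects(HAS_ROLE_IRI):
            if isinstance(s, URIRef) and isinstance(o, URIRef):
                snap.roles.setdefault(str(s), set()).add(str(o))
        snap.role_form = "annotation" if snap.roles else None
    logger.info("role linkage axiom shape: %s", snap.role_form or "none found")
    return snap


def _load_obo(path: Path) -> ChebiSnapshot:
    import obonet

    graph = obonet.read_obo(str(path))
    snap = ChebiSnapshot()

    def to_iri(obo_id: str) -> str:
        return OBO + obo_id.replace(":", "_")

    syn_re = re.compile(r'"(.*)"\s+(EXACT|RELATED)')
    for node, data in graph.nodes(data=True):
        iri = to_iri(node)
        snap.labels[iri] = data.get("name", "")
        for syn in data.get("synonym", []):
            m = syn_re.match(syn)
            if not m:
                continue
            text, scope = m.groups()
            target = snap.exact_synonyms if scope == "EXACT" else snap.related_synonyms
            target.setdefault(iri, set()).add(text)
        for parent in data.get("is_a", []):
            snap.parents.setdefault(iri, set()).add(to_iri(parent))
        for rel in data.get("relationship", []):
            parts = rel.split()
            if len(parts) == 2 and parts[0] == "has_role":
                snap.roles.setdefault(iri, set()).add(to_iri(parts[1]))
    snap.role_form = "annotation" if snap.roles else None
    return snap


# ---------------------------------------------------------------------------
# Lexical index and matching
# ---------------------------------------------------------------------------

#: normalized name -> set of (class IRI, annotation type)
LexicalIndex = dict[str, set[tuple[str, str]]]


def build_index(snapshot: ChebiSnapshot) -> LexicalIndex:
    """Index every class by its normalized label and synonyms."""
    index: LexicalIndex = {}

    def add(name: str, iri: str, ann: str) -> None:
        if name:
            index.setdefault(normalize_name(name), set()).add((iri, ann))

    for iri, label in snapshot.labels.items():
        if label:
            add(label, iri, "label")
        elif iri in snapshot.exact_synonyms or iri in snapshot.related_synonyms:
            logger.warning("class %s has no label; indexed by synonyms only", iri)
        for syn in snapshot.exact_synonyms.get(iri, ()):
            add(syn, iri, "exact_synonym")
        for syn in snapshot.related_synonyms.get(iri, ()):
            add(syn, iri, "related_synonym")
    return index


@dataclass(frozen=True)
class IngredientMapping:
    """Where one ingredient's class IRI comes from.

    ``source`` is CHEBI / PRO for reused external IRIs and DRON for
    ingredients that get a freshly minted IRI (``matched_via == 'none'``).
    """
    rxcui: str
    target_iri: str | None
    source: str          # "CHEBI" | "PRO" | "DRON"
    matched_via: str     # annotation type | "override" | "none"

    def __post_init__(self) -> None:
        if (self.source == "DRON") != (self.matched_via == "none"):
            raise ValueError("DRON-minted mappings must (only) have matched_via='none'")


def _source_for_iri(iri: str) -> str:
    return "PRO" if "/PR_" in iri else "CHEBI"


def match_ingredient(
    atom: Atom,
    index: LexicalIndex,
    overrides: dict[str, str] | None = None,
    report: list[dict] | None = None,
) -> IngredientMapping:
    """Map one ingredient atom to an external class IRI, if any.

    Overrides (normalized name -> IRI) win outright.  Otherwise the
    normalized name is looked up in the index; among hits, a label match
    beats synonym matches.  If the winning annotation type still offers
    two or more distinct IRIs the match is rejected to the curation
    *report* and the ingredient falls through to a minted IRI.
    """
    if atom.tty != "IN":
        raise ValueError(f"match_ingredient expects an IN atom, got tty={atom.tty}")
    name = normalize_name(atom.name)
    if overrides and name in overrides:
        iri = overrides[name]
        return IngredientMapping(atom.rxcui, iri, _source_for_iri(iri), "override")
    hits = index.get(name, set())
    for ann in ANNOTATION_TYPES:
        iris = sorted({iri for iri, a in hits if a == ann})
        if not iris:
            continue
        if len(iris) == 1:
            return IngredientMapping(atom.rxcui, iris[0], _source_for_iri(iris[0]), ann)
        logger.warning("ambiguous %s match for %r: %s; deferring to curation",
                       ann, atom.name, iris)
        if report is not None:
            report.append({"rxcui": atom.rxcui, "name": atom.name,
                           "annotation": ann, "candidates": iris})
        break
    return IngredientMapping(atom.rxcui, None, "DRON", "none")


def match_tally(mappings: "list[IngredientMapping] | dict[str, IngredientMapping]") -> dict[str, int]:
    """Count matches per annotation type (plus override / none)."""
    values = mappings.values() if isinstance(mappings, dict) else mappings
    tally = {ann: 0 for ann in ANNOTATION_TYPES} | {"override": 0, "none": 0}
    for m in values:
        tally[m.matched_via] += 1
    return tally


# ---------------------------------------------------------------------------
# Superclass closure import
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class ClosureRecord:
    iri: str
    label: str
    parents: tuple[str, ...]  # restricted to parents inside the closure


def import_closure(matched_iris: set[str], snapshot: ChebiSnapshot) -> list[ClosureRecord]:
    """Matched classes plus all their is-a ancestors, with in-set edges.

    Ancestors are collected by graph reachability over asserted named
    superclasses; dangling parent references (IRIs the snapshot never
    declares) are logged and their edges dropped.  The result is
    ancestor-closed: every kept parent is itself a returned class.
    """
    known = snapshot.classes()
    closure: set[str] = set()
    stack = [i for i in matched_iris]
    while stack:
        iri = stack.pop()
        if iri in closure:
            continue
        closure.add(iri)
        for parent in snapshot.parents.get(iri, ()):
            if parent not in known:
                logger.warning("dangling parent %s of %s; edge dropped", parent, iri)
                continue
            stack.append(parent)
    return sorted(
        ClosureRecord(
            iri=iri,
            label=snapshot.labels.get(iri, ""),
            parents=tuple(sorted(p for p in snapshot.parents.get(iri, ()) if p in closure)),
        )
        for iri in closure
    )


# ---------------------------------------------------------------------------
# Disposition–ingredient mining
# ---------------------------------------------------------------------------

@dataclass
class RoleMap:
    """The six dispositions and where their ingredient links come from.

    Exactly three dispositions map to a ChEBI role (mined from role
    assignments); the other three carry manually curated ingredient lists.
    Curated entries and exclusions reference ingredients by identifier or
    by normalized name.  Exclusions remove mined links that are too coarse
    (ChEBI's 'calcium channel blocker' covers both L-type and T-type
    blockers; ethosuximide is excluded from the L-type disposition and
    curated onto the T-type one).
    """
    chebi_roles: dict[str, str]                 # disposition label -> role IRI
    curated: dict[str, list[str]]               # disposition label -> ingredient refs
    exclusions: set[tuple[str, str]] = field(default_factory=set)
    dispositions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.dispositions:
            self.dispositions = tuple(sorted(set(self.chebi_roles) | set(self.curated)))
        if len(self.dispositions) != 6:
            raise ValueError(f"expected exactly six dispositions, got {len(self.dispositions)}")
        if len(self.chebi_roles) != 3:
            raise ValueError("exactly three dispositions must carry ChEBI roles")


def _descendants(snapshot: ChebiSnapshot, root: str) -> set[str]:
    children: dict[str, set[str]] = {}
    for child, parents in snapshot.parents.items():
        for p in parents:
            children.setdefault(p, set()).add(child)
    out, stack = {root}, [root]
    while stack:
        node = stack.pop()
        for c in children.get(node, ()):
            if c not in out:
                out.add(c)
                stack.append(c)
    return out


def mine_roles(
    snapshot: ChebiSnapshot,
    role_map: RoleMap,
    mappings: dict[str, IngredientMapping],
    names: dict[str, str],
) -> set[tuple[str, str]]:
    """Derive (disposition label, ingredient identifier) links.

    For each role-backed disposition, every mapped ingredient whose ChEBI
    class bears that role (or a sub-role of it) is linked.  Curated
    dispositions contribute their lists verbatim, matched by identifier or
    normalized name; exclusions are then removed.
    """
    links: set[tuple[str, str]] = set()
    iri_to_rxcuis: dict[str, set[str]] = {}
    for rxcui, m in mappings.items():
        if m.target_iri:
            iri_to_rxcuis.setdefault(m.target_iri, set()).add(rxcui)

    for disposition, role_iri in role_map.chebi_roles.items():
        if role_iri not in snapshot.classes():
            raise RoleNotFoundError(
                f"role {role_iri!r} for disposition {disposition!r} is absent from the snapshot"
            )
        acceptable = _descendants(snapshot, role_iri)
        for iri, rxcuis in iri_to_rxcuis.items():
            if snapshot.roles.get(iri, set()) & acceptable:
                links.update((disposition, r) for r in rxcuis)

    by_name = {normalize_name(n): rxcui for rxcui, n in names.items()}

    def find(ref: str) -> str | None:
        if ref in names:
            return ref
        return by_name.get(normalize_name(ref))

    for disposition, refs in role_map.curated.items():
        for ref in refs:
            rxcui = find(ref)
            if rxcui is not None:
                links.add((disposition, rxcui))

    for disposition, ref in role_map.exclusions:
        rxcui = find(ref)
        if rxcui is not None:
            links.discard((disposition, rxcui))
    return links


# ---------------------------------------------------------------------------
# Shipped seed content
# ---------------------------------------------------------------------------

def _read_tsv(name: str, path: str | Path | None = None) -> list[list[str]]:
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
    else:
        text = resources.files("dronbuild.data").joinpath(name).read_text(encoding="utf-8")
    rows = []
    for row in csv.reader(text.splitlines(), delimiter="\t"):
        if row and not row[0].startswith("#"):
            rows.append(row)
    return rows


def load_overrides(path: str | Path | None = None) -> dict[str, str]:
    """Manual mapping overrides: normalized ingredient name -> IRI."""
    return {normalize_name(r[0]): r[1] for r in _read_tsv("overrides.tsv", path)}


def load_role_map(
    dispositions_path: str | Path | None = None,
    curated_path: str | Path | None = None,
    exclusions_path: str | Path | None = None,
) -> RoleMap:
    """Load the shipped six-disposition role map and curated lists."""
    chebi_roles: dict[str, str] = {}
    dispositions: list[str] = []
    for row in _read_tsv("dispositions.tsv", dispositions_path):
        dispositions.append(row[0])
        if len(row) > 1 and row[1]:
            chebi_roles[row[0]] = row[1]
    curated: dict[str, list[str]] = {d: [] for d in dispositions if d not in chebi_roles}
    for row in _read_tsv("curated_disposition_ingredients.tsv", curated_path):
        curated.setdefault(row[0], []).append(row[1])
    exclusions = {(r[0], r[1]) for r in _read_tsv("disposition_exclusions.tsv", exclusions_path)}
    return RoleMap(chebi_roles=chebi_roles, curated=curated,
                   exclusions=exclusions, dispositions=tuple(dispositions))
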