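"""The normalized entity model and its relational export.

Six entity types are derived from the release series: ingredients,
dispositions, clinical drug forms (CDFs, from SCDF atoms), clinical drugs
(CDs, from SCD atoms), branded drugs (BDs, from SBD atoms), and packaged
drug products (one per historically observed NDC).  Entities are keyed by
*terminal* identifier, so concepts merged over the series collapse into a
single entity automatically.

Export to the relational store follows four steps: (1) initialize the
identifier and release tables from the compacted provenance table, (2)
copy the deduplicated NDC list, (3) create the ingredient/CDF/CD/BD
entities with their relationships, (4) attach each NDC as a packaged
product under its CD or BD by following the identifier provenance trail.

The store also answers the validating use-case queries: all NDCs whose
product contains a given ingredient, or an ingredient bearing a given
disposition.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .chebi_mapper import IngredientMapping, RoleMap
from .ndc_registry import NdcRegistry, NdcStatus
from .provenance import ProvenanceTable, Resolution, ResolutionKind, resolve
from .rrf_io import (
    REL_HAS_INGREDIENT,
    REL_ISA,
    REL_TRADENAME_OF,
    Atom,
    ReleaseVersion,
)

logger = logging.getLogger(__name__)


class GraphInvariantError(ValueError):
    """The entity graph violates a structural invariant."""


@dataclass
class Ingredient:
    rxcui: str
    name: str
    mapping: IngredientMapping | None = None
    orphaned: bool = False


@dataclass
class Cdf:
    rxcui: str
    name: str
    ingredients: set[str] = field(default_factory=set)
    orphaned: bool = False


@dataclass
class Cd:
    rxcui: str
    name: str
    parent_cdf: str | None = None  # None = dangling (kept, flagged)
    orphaned: bool = False


@dataclass
class Bd:
    rxcui: str
    name: str
    parent_cd: str | None = None
    orphaned: bool = False


@dataclass
class PackagedProduct:
    """The entity an NDC denotes: a package of drug-product instances."""
    ndc: str
    parent_rxcui: str
    parent_kind: str  # "CD" | "BD"
    orphaned: bool = False


@dataclass
class EntityGraph:
    ingredients: dict[str, Ingredient] = field(default_factory=dict)
    dispositions: tuple[str, ...] = ()
    cdfs: dict[str, Cdf] = field(default_factory=dict)
    cds: dict[str, Cd] = field(default_factory=dict)
    bds: dict[str, Bd] = field(default_factory=dict)
    packaged: dict[str, PackagedProduct] = field(default_factory=dict)
    disposition_bearers: set[tuple[str, str]] = field(default_factory=set)
    unattachable: list[tuple[str, str]] = field(default_factory=list)  # (ndc, rxcui)

    def entity_counts(self) -> dict[str, int]:
        return {
            "ingredients": len(self.ingredients),
            "dispositions": len(self.dispositions),
            "cdfs": len(self.cdfs),
            "cds": len(self.cds),
            "bds": len(self.bds),
            "packaged": len(self.packaged),
        }


# ---------------------------------------------------------------------------
# Step 3: entity creation
# ---------------------------------------------------------------------------

def build_entities(
    atoms: Iterable[tuple[Atom, int]],
    relationships: Iterable[tuple[tuple[str, str, str], int]],
    mappings: dict[str, IngredientMapping],
    table: ProvenanceTable,
    role_map: RoleMap | None = None,
    disposition_links: set[tuple[str, str]] | None = None,
) -> EntityGraph:
    """Create one entity per (terminal identifier, type) from all releases.

    *atoms* and *relationships* carry the release ordinal they were seen
    in.  Identifiers are resolved through the compacted provenance table:
    atoms resolving to ERROR or split are skipped; merged atoms collapse
    onto their terminal identifier (names from the latest release win,
    preferring the terminal identifier's own atom).  Relationship
    endpoints are remapped the same way; edges touching an ERROR/split
    endpoint are dropped and logged.  Single-valued parents keep the edge
    from the latest release.
    """
    graph = EntityGraph()
    if role_map is not None:
        graph.dispositions = role_map.dispositions
    cache: dict[str, Resolution] = {}

    def res(rxcui: str) -> Resolution:
        if rxcui not in cache:
            cache[rxcui] = resolve(rxcui, table)
        return cache[rxcui]

    # pick one name per (terminal, tty): latest ordinal, terminal's own atom wins ties
    namepick: dict[tuple[str, str], tuple[tuple[int, int], str, bool]] = {}
    for atom, ordinal in atoms:
        r = res(atom.rxcui)
        if r.kind in (ResolutionKind.ERROR, ResolutionKind.SPLIT):
            continue
        assert r.terminal is not None
        key = (r.terminal, atom.tty)
        rank = (ordinal, 1 if atom.rxcui == r.terminal else 0)
        prev = namepick.get(key)
        if prev is None or rank > prev[0]:
            namepick[key] = (rank, atom.name, r.kind is ResolutionKind.ORPHANED)

    for (terminal, tty), (_, name, orphaned) in namepick.items():
        if tty == "IN":
            graph.ingredients[terminal] = Ingredient(
                terminal, name, mappings.get(terminal), orphaned)
        elif tty == "SCDF":
            graph.cdfs[terminal] = Cdf(terminal, name, orphaned=orphaned)
        elif tty == "SCD":
            graph.cds[terminal] = Cd(terminal, name, orphaned=orphaned)
        elif tty == "SBD":
            graph.bds[terminal] = Bd(terminal, name, orphaned=orphaned)

    # remap relationship endpoints; keep latest release for 1-valued parents
    parent_pick: dict[tuple[str, str], tuple[tuple[int, int], str]] = {}
    for (a, rel, b), ordinal in relationships:
        ra, rb = res(a), res(b)
        if ra.terminal is None or rb.terminal is None:
            logger.info("dropping %s edge %s->%s: endpoint retired as error/split", rel, a, b)
            continue
        ta, tb = ra.terminal, rb.terminal
        if rel == REL_HAS_INGREDIENT:
            target = graph.cdfs.get(ta)
            if target is not None and tb in graph.ingredients:
                target.ingredients.add(tb)
        elif rel in (REL_ISA, REL_TRADENAME_OF):
            rank = (ordinal, 1 if a == ta else 0)
            key = (rel, ta)
            prev = parent_pick.get(key)
            if prev is None or rank > prev[0]:
                if prev is not None and prev[1] != tb:
                    logger.info("conflicting %s parents for %s: %s vs %s; keeping latest",
                                rel, ta, prev[1], tb)
                parent_pick[key] = (rank, tb)

    for (rel, child), (_, parent) in parent_pick.items():
        if rel == REL_ISA and child in graph.cds and parent in graph.cdfs:
            graph.cds[child].parent_cdf = parent
        elif rel == REL_TRADENAME_OF and child in graph.bds and parent in graph.cds:
            graph.bds[child].parent_cd = parent

    for cd in graph.cds.values():
        if cd.parent_cdf is None:
            logger.warning("clinical drug %s has no drug-form parent; kept dangling", cd.rxcui)

    if disposition_links:
        known = set(graph.dispositions)
        for disposition, rxcui in disposition_links:
            if disposition in known and rxcui in graph.ingredients:
                graph.disposition_bearers.add((disposition, rxcui))
    return graph


# ---------------------------------------------------------------------------
# Step 4: NDC attachment
# ---------------------------------------------------------------------------

def attach_ndcs(
    graph: EntityGraph,
    ndc_rows: Iterable[tuple[str, str]],
    orphaned_codes: set[str] | None = None,
) -> EntityGraph:
    """Attach each (ndc, resolved identifier) row as a packaged product.

    The row's identifier must name a CD or BD entity; rows resolving to an
    ingredient, drug form, or nothing at all are reported unattachable.
    """
    orphaned_codes = orphaned_codes or set()
    for ndc, rxcui in ndc_rows:
        if rxcui in graph.bds:
            kind = "BD"
        elif rxcui in graph.cds:
            kind = "CD"
        else:
            graph.unattachable.append((ndc, rxcui))
            logger.warning("NDC %s resolves to %s, which is no drug product; unattachable",
                           ndc, rxcui)
            continue
        graph.packaged[ndc] = PackagedProduct(ndc, rxcui, kind, ndc in orphaned_codes)
    return graph


def validate_graph(graph: EntityGraph) -> None:
    """Assert the structural invariants; raise GraphInvariantError on failure."""
    for bd in graph.bds.values():
        if bd.parent_cd is not None and bd.parent_cd not in graph.cds:
            raise GraphInvariantError(f"branded drug {bd.rxcui} parents unknown CD {bd.parent_cd}")
    for cd in graph.cds.values():
        if cd.parent_cdf is not None and cd.parent_cdf not in graph.cdfs:
            raise GraphInvariantError(f"clinical drug {cd.rxcui} parents unknown CDF {cd.parent_cdf}")
    for cdf in graph.cdfs.values():
        for ing in cdf.ingredients:
            if ing not in graph.ingredients:
                raise GraphInvariantError(f"drug form {cdf.rxcui} lists unknown ingredient {ing}")
    for pkg in graph.packaged.values():
        pool = graph.bds if pkg.parent_kind == "BD" else graph.cds
        if pkg.parent_rxcui not in pool:
            raise GraphInvariantError(f"packaged product {pkg.ndc} parents unknown {pkg.parent_kind}")
    for disposition, rxcui in graph.disposition_bearers:
        if disposition not in graph.dispositions:
            raise GraphInvariantError(f"unknown disposition {disposition!r}")
        if rxcui not in graph.ingredients:
            raise GraphInvariantError(f"disposition bearer {rxcui} is no ingredient")


# ---------------------------------------------------------------------------
# Validation queries
# ---------------------------------------------------------------------------

def query_ndcs_by_ingredient(graph: EntityGraph, ingredient: str) -> set[str]:
    """All NDC codes of packaged products containing *ingredient*.

    The ingredient may be given as identifier or (normalized) name.  A
    packaged product qualifies when its parent CD/BD descends from a CDF
    that lists the ingredient.
    """
    from .chebi_mapper import normalize_name

    rxcui = ingredient
    if rxcui not in graph.ingredients:
        wanted = normalize_name(ingredient)
        matches = [i.rxcui for i in graph.ingredients.values()
                   if normalize_name(i.name) == wanted]
        if not matches:
            logger.warning("unknown ingredient %r", ingredient)
            return set()
        rxcui = matches[0]
    cdfs = {c.rxcui for c in graph.cdfs.values() if rxcui in c.ingredients}
    cds = {c.rxcui for c in graph.cds.values() if c.parent_cdf in cdfs}
    bds = {b.rxcui for b in graph.bds.values() if b.parent_cd in cds}
    return {
        p.ndc for p in graph.packaged.values()
        if (p.parent_kind == "CD" and p.parent_rxcui in cds)
        or (p.parent_kind == "BD" and p.parent_rxcui in bds)
    }


def query_ndcs_by_disposition(graph: EntityGraph, disposition: str) -> set[str]:
    """All NDC codes whose product contains an ingredient bearing *disposition*."""
    bearers = {r for d, r in graph.disposition_bearers if d == disposition}
    if not bearers and disposition not in graph.dispositions:
        logger.warning("unknown disposition %r", disposition)
    out: set[str] = set()
    for rxcui in bearers:
        out |= query_ndcs_by_ingredient(graph, rxcui)
    return out


# ---------------------------------------------------------------------------
# Relational export (sqlite)
# ---------------------------------------------------------------------------

_SCHEMA = """
CREATE TABLE rxnorm (ordinal INTEGER PRIMARY KEY, version TEXT NOT NULL);
CREATE TABLE rxcui (
    rxcui TEXT PRIMARY KEY, terminal TEXT, status TEXT NOT NULL, orphaned INTEGER NOT NULL
);
CREATE TABLE deprecated_rxcuis (old_rxcui TEXT PRIMARY KEY, new_rxcui TEXT NOT NULL,
                                orphaned INTEGER NOT NULL);
CREATE TABLE ndc (ndc TEXT PRIMARY KEY, rxcui TEXT NOT NULL, orphaned INTEGER NOT NULL);
CREATE TABLE ndc_comp (ndc TEXT, rxcui TEXT, first_seen TEXT, last_seen TEXT, status TEXT,
                       PRIMARY KEY (ndc, rxcui));
CREATE TABLE ingredient (rxcui TEXT PRIMARY KEY, name TEXT, target_iri TEXT,
                         source TEXT, matched_via TEXT, orphaned INTEGER NOT NULL);
CREATE TABLE clinical_drug_form (rxcui TEXT PRIMARY KEY, name TEXT, orphaned INTEGER NOT NULL);
CREATE TABLE clinical_drug (rxcui TEXT PRIMARY KEY, name TEXT, parent_cdf TEXT,
                            orphaned INTEGER NOT NULL);
CREATE TABLE branded_drug (rxcui TEXT PRIMARY KEY, name TEXT, parent_cd TEXT,
                           orphaned INTEGER NOT NULL);
CREATE TABLE disposition (label TEXT PRIMARY KEY, chebi_role_iri TEXT);
CREATE TABLE packaged_product (ndc TEXT PRIMARY KEY, parent_rxcui TEXT NOT NULL,
                               parent_kind TEXT NOT NULL, orphaned INTEGER NOT NULL);
CREATE TABLE cdf_ingredient (cdf_rxcui TEXT, ingredient_rxcui TEXT,
                             PRIMARY KEY (cdf_rxcui, ingredient_rxcui));
CREATE TABLE disposition_ingredient (disposition TEXT, ingredient_rxcui TEXT,
                                     PRIMARY KEY (disposition, ingredient_rxcui));
"""


def init_provenance_tables(
    conn: sqlite3.Connection,
    table: ProvenanceTable,
    versions: Iterable[ReleaseVersion],
) -> None:
    """Export step 1: the identifier and release-version tables."""
    if not table.compacted:
        raise ValueError("provenance table must be compacted before export")
    conn.executemany("INSERT INTO rxnorm VALUES (?, ?)",
                     sorted((v.ordinal, v.label) for v in versions))
    rows = []
    seen: set[str] = set()
    for ident in sorted(table.observed_current):
        rows.append((ident, ident, "CURRENT", 0))
        seen.add(ident)
    for old, new in sorted(table.entries.items()):
        res = resolve(old, table)
        rows.append((old, res.terminal, res.kind.value, int(old in table.orphaned)))
        seen.add(old)
        conn.execute("INSERT INTO deprecated_rxcuis VALUES (?, ?, ?)",
                     (old, new, int(old in table.orphaned)))
    conn.executemany("INSERT INTO rxcui VALUES (?, ?, ?, ?)", rows)


def init_ndc_table(conn: sqlite3.Connection, registry: NdcRegistry) -> None:
    """Export step 2: the deduplicated NDC list plus the full audit table."""
    from .ndc_registry import included_ndcs, orphaned_ndcs

    pairs = included_ndcs(registry)
    orphans = orphaned_ndcs(registry)
    conn.executemany("INSERT INTO ndc VALUES (?, ?, ?)",
                     sorted((ndc, rxcui, int(ndc in orphans)) for ndc, rxcui in pairs))
    conn.executemany(
        "INSERT INTO ndc_comp VALUES (?, ?, ?, ?, ?)",
        sorted((e.ndc, e.original_rxcui, e.first_seen.label, e.last_seen.label,
                e.status.value if e.status else "")
               for e in registry.entries.values()),
    )


def export_db(
    path: str | Path,
    graph: EntityGraph,
    table: ProvenanceTable,
    registry: NdcRegistry,
    versions: Iterable[ReleaseVersion],
    role_map: RoleMap | None = None,
) -> None:
    """Write the full normalized store to a single-file sqlite database."""
    path = Path(path)
    if path.exists():
        path.unlink()
    conn = sqlite3.connect(path)
    try:
        conn.executescript(_SCHEMA)
        init_provenance_tables(conn, table, versions)
        init_ndc_table(conn, registry)
        conn.executemany(
            "INSERT INTO ingredient VALUES (?, ?, ?, ?, ?, ?)",
            sorted((i.rxcui, i.name,
                    i.mapping.target_iri if i.mapping else None,
                    i.mapping.source if i.mapping else "DRON",
                    i.mapping.matched_via if i.mapping else "none",
                    int(i.orphaned))
                   for i in graph.ingredients.values()),
        )
        conn.executemany("INSERT INTO clinical_drug_form VALUES (?, ?, ?)",
                         sorted((c.rxcui, c.name, int(c.orphaned)) for c in graph.cdfs.values()))
        conn.executemany("INSERT INTO clinical_drug VALUES (?, ?, ?, ?)",
                         sorted((c.rxcui, c.name, c.parent_cdf, int(c.orphaned))
                                for c in graph.cds.values()))
        conn.executemany("INSERT INTO branded_drug VALUES (?, ?, ?, ?)",
                         sorted((b.rxcui, b.name, b.parent_cd, int(b.orphaned))
                                for b in graph.bds.values()))
        conn.executemany("INSERT INTO packaged_product VALUES (?, ?, ?, ?)",
                         sorted((p.ndc, p.parent_rxcui, p.parent_kind, int(p.orphaned))
                                for p in graph.packaged.values()))
        conn.executemany("INSERT INTO cdf_ingredient VALUES (?, ?)",
                         sorted((c.rxcui, i) for c in graph.cdfs.values()
                                for i in c.ingredients))
        conn.executemany("INSERT INTO disposition_ingredient VALUES (?, ?)",
                         sorted(graph.disposition_bearers))
        dispositions = graph.dispositions
        roles = role_map.chebi_roles if role_map else {}
        conn.executemany("INSERT INTO disposition VALUES (?, ?)",
                         sorted((d, roles.get(d)) for d in dispositions))
        conn.commit()
    finally:
        conn.close()


def load_graph(path: str | Path) -> EntityGraph:
    """Rebuild an :class:`EntityGraph` from an exported sqlite store."""
    conn = sqlite3.connect(Path(path))
    try:
        graph = EntityGraph()
        for rxcui, name, iri, source, via, orph in conn.execute("SELECT * FROM ingredient"):
            mapping = None
            if via != "none":
                mapping = IngredientMapping(rxcui, iri, source, via)
            graph.ingredients[rxcui] = Ingredient(rxcui, name, mapping, bool(orph))
        for rxcui, name, orph in conn.execute("SELECT * FROM clinical_drug_form"):
            graph.cdfs[rxcui] = Cdf(rxcui, name, orphaned=bool(orph))
        for cdf, ing in conn.execute("SELECT * FROM cdf_ingredient"):
            graph.cdfs[cdf].ingredients.add(ing)
        for rxcui, name, parent, orph in conn.execute("SELECT * FROM clinical_drug"):
            graph.cds[rxcui] = Cd(rxcui, name, parent, bool(orph))
        for rxcui, name, parent, orph in conn.execute("SELECT * FROM branded_drug"):
            graph.bds[rxcui] = Bd(rxcui, name, parent, bool(orph))
        for ndc, parent, kind, orph in conn.execute("SELECT * FROM packaged_product"):
            graph.packaged[ndc] = PackagedProduct(ndc, parent, kind, bool(orph))
        graph.dispositions = tuple(
            d for (d,) in conn.execute("SELECT label FROM disposition ORDER BY label"))
        for d, i in conn.execute("SELECT * FROM disposition_ingredient"):
            graph.disposition_bearers.add((d, i))
        return graph
    finally:
        conn.close()
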