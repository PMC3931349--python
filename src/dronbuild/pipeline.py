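"""End-to-end orchestration: release series in, five OWL modules out.

The stages run strictly in order: (1) parse each release directory, in
chronological order; (2) maintain the identifier provenance table and the
historical NDC registry incrementally per release; (3) compact the
provenance chains and finalize the registry; (4) map ingredient entities
to ChEBI/PRO classes and mine disposition links; (5) build the normalized
entity graph and attach the NDCs; (6) optionally export the relational
store and emit the OWL module set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import chebi_mapper, ndc_registry, normalized_store, owl_emitter, provenance
from .chebi_mapper import ChebiSnapshot, IngredientMapping, RoleMap
from .ndc_registry import NdcRegistry
from .normalized_store import EntityGraph
from .owl_emitter import OntologyModuleSet
from .provenance import ProvenanceTable, ResolutionKind
from .rrf_io import Atom, ReleaseSnapshot, read_release

logger = logging.getLogger(__name__)

PRO_PROTEIN_ROOT = "http://purl.obolibrary.org/obo/PR_000000001"


@dataclass
class PipelineResult:
    snapshots: list[ReleaseSnapshot]
    table: ProvenanceTable
    registry: NdcRegistry
    mappings: dict[str, IngredientMapping]
    role_map: RoleMap
    disposition_links: set[tuple[str, str]]
    graph: EntityGraph
    modules: OntologyModuleSet
    match_tally: dict[str, int]
    curation_report: list[dict] = field(default_factory=list)


def ingest_series(
    snapshots: list[ReleaseSnapshot],
) -> tuple[ProvenanceTable, NdcRegistry]:
    """Run the per-release provenance and registry maintenance, then compact.

    Releases must arrive in chronological order (strictly increasing
    ordinals); out-of-order input is refused.
    """
    ordinals = [s.version.ordinal for s in snapshots]
    if ordinals != sorted(ordinals) or len(set(ordinals)) != len(ordinals):
        raise ValueError(f"releases must be ingested in chronological order, got {ordinals}")
    table = ProvenanceTable()
    registry = NdcRegistry()
    known: set[str] = set()
    for snap in snapshots:
        provenance.update_for_release(table, known, snap)
        ndc_registry.accumulate(registry, snap)
        known |= snap.atom_rxcuis()
        known |= {a.rxcui for a in snap.ndc_attributes}
    provenance.compact_closure(table)
    ndc_registry.finalize(registry, table)
    return table, registry


def _terminal_ingredients(
    snapshots: list[ReleaseSnapshot], table: ProvenanceTable
) -> dict[str, str]:
    """Name per terminal ingredient identifier (latest release wins)."""
    pick: dict[str, tuple[tuple[int, int], str]] = {}
    for snap in snapshots:
        for atom in snap.atoms:
            if atom.tty != "IN":
                continue
            res = provenance.resolve(atom.rxcui, table)
            if res.kind in (ResolutionKind.ERROR, ResolutionKind.SPLIT):
                continue
            rank = (snap.version.ordinal, 1 if atom.rxcui == res.terminal else 0)
            prev = pick.get(res.terminal)
            if prev is None or rank > prev[0]:
                pick[res.terminal] = (rank, atom.name)
    return {rxcui: name for rxcui, (_, name) in pick.items()}


def map_ingredients(
    snapshots: list[ReleaseSnapshot],
    table: ProvenanceTable,
    chebi: ChebiSnapshot | None,
    overrides: dict[str, str] | None = None,
    role_map: RoleMap | None = None,
    report: list[dict] | None = None,
) -> tuple[dict[str, IngredientMapping], set[tuple[str, str]], dict[str, str]]:
    """Match every terminal ingredient and derive disposition links."""
    overrides = chebi_mapper.load_overrides() if overrides is None else overrides
    role_map = role_map or chebi_mapper.load_role_map()
    names = _terminal_ingredients(snapshots, table)
    index = chebi_mapper.build_index(chebi) if chebi is not None else {}
    mappings = {
        rxcui: chebi_mapper.match_ingredient(Atom(rxcui, "IN", name), index,
                                             overrides, report)
        for rxcui, name in names.items()
    }
    if chebi is not None:
        links = chebi_mapper.mine_roles(chebi, role_map, mappings, names)
    else:
        links = chebi_mapper.mine_roles(ChebiSnapshot(
            labels={iri: "" for iri in role_map.chebi_roles.values()}),
            role_map, mappings, names)
    return mappings, links, names


def run_pipeline(
    release_dirs: list[str | Path],
    chebi_path: str | Path | None = None,
    overrides_path: str | Path | None = None,
    out_db: str | Path | None = None,
    out_owl: str | Path | None = None,
    strict: bool = True,
) -> PipelineResult:
    """Build everything from a chronologically ordered list of releases."""
    snapshots = [read_release(d, ordinal=i + 1, strict=strict)
                 for i, d in enumerate(release_dirs)]
    table, registry = ingest_series(snapshots)

    chebi = chebi_mapper.load_ontology(chebi_path) if chebi_path else None
    overrides = (chebi_mapper.load_overrides(overrides_path)
                 if overrides_path else chebi_mapper.load_overrides())
    role_map = chebi_mapper.load_role_map()
    report: list[dict] = []
    mappings, links, _names = map_ingredients(
        snapshots, table, chebi, overrides, role_map, report)

    atoms = [(a, s.version.ordinal) for s in snapshots for a in s.atoms]
    rels = [(t, s.version.ordinal) for s in snapshots for t in s.relationships]
    graph = normalized_store.build_entities(atoms, rels, mappings, table,
                                            role_map, links)
    pairs = ndc_registry.included_ndcs(registry)
    orphans = ndc_registry.orphaned_ndcs(registry)
    normalized_store.attach_ndcs(graph, pairs, orphans)
    normalized_store.validate_graph(graph)

    matched_chebi = {m.target_iri for m in mappings.values()
                     if m.source == "CHEBI" and m.target_iri}
    closure = (chebi_mapper.import_closure(matched_chebi, chebi)
               if chebi is not None else [])
    pro_iris = sorted({m.target_iri for m in mappings.values()
                       if m.source == "PRO" and m.target_iri})
    pro_stubs: list[tuple[str, str, str | None]] = []
    if pro_iris:
        pro_stubs.append((PRO_PROTEIN_ROOT, "protein", None))
        by_iri = {m.target_iri: m.rxcui for m in mappings.values() if m.source == "PRO"}
        pro_names = {rxcui: name for rxcui, name in _names.items()}
        for iri in pro_iris:
            pro_stubs.append((iri, pro_names.get(by_iri[iri], ""), PRO_PROTEIN_ROOT))

    curated = owl_emitter.load_curated_upper()
    modules = owl_emitter.emit(graph, curated, closure, pro_stubs)

    if out_db is not None:
        versions = [s.version for s in snapshots]
        normalized_store.export_db(out_db, graph, table, registry, versions, role_map)
    if out_owl is not None:
        owl_emitter.write_modules(modules, out_owl)

    return PipelineResult(
        snapshots=snapshots, table=table, registry=registry, mappings=mappings,
        role_map=role_map, disposition_links=links, graph=graph, modules=modules,
        match_tally=chebi_mapper.match_tally(mappings), curation_report=report,
    )
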