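"""Deterministic synthetic release series and mini-ChEBI snapshots.

Real releases of the source terminology are license-restricted, so every
pipeline stage is exercised against generated fixtures instead: a
chronological series of release directories in the RRF dialect plus a
small ChEBI-style ontology, together with a ground-truth manifest stating
what the pipeline must produce — the terminal provenance mapping, the
status of every NDC observation, entity counts per type, per-module class
counts, lexical-match tallies, disposition links, and designated query
answers.

The series injects the identifier lifecycle events the provenance tracker
must handle: merges (retirement record with cardinality 1, including
chained re-retirements), identifiers entered in error (record with
``cui1 == cui2``), splits (cardinality 2), and silent disappearances (the
atom vanishes with no record at all).  The mini-ChEBI contains classes
matchable via each annotation type, a role hierarchy with links to
designated ingredient classes, the furosemide class at its canonical
accession, and a 'growth hormone' *role* whose synonym collides with the
ingredient somatropin — the trap the shipped manual override defuses.

All randomness is drawn once, from the config seed, while building an
explicit plan; the writers are pure functions of that plan, so a config
generates byte-identical fixtures on every run.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import rdflib
from rdflib import OWL, RDF, RDFS, BNode, Literal, URIRef
from pydantic import BaseModel, Field, model_validator

from .chebi_mapper import EXACT_SYN_IRI, HAS_ROLE_IRI, RELATED_SYN_IRI, OBO
from .rrf_io import (
    NDC_ATN,
    REL_HAS_INGREDIENT,
    REL_ISA,
    REL_TRADENAME_OF,
    RXNCONSO_SCHEMA,
    RXNORM_SAB,
    RXNSAT_SCHEMA,
    Atom,
    NdcAttribute,
    ReleaseSnapshot,
    ReleaseVersion,
    RetirementRecord,
    write_release,
)

#: Synthetic identifier ranges, disjoint from real concept identifiers.
_IN_BASE, _CDF_BASE, _CD_BASE, _BD_BASE = 9_000_000, 9_100_000, 9_200_000, 9_300_000

FUROSEMIDE_CHEBI = OBO + "CHEBI_47426"
#: Real ChEBI accessions for the three mined roles (and the role root).
ROLE_ROOT = OBO + "CHEBI_50906"
BETA_ROLE = OBO + "CHEBI_35530"          # beta-adrenergic antagonist
PPI_ROLE = OBO + "CHEBI_49200"           # proton pump inhibitor
CCB_ROLE = OBO + "CHEBI_38808"           # calcium channel blocker
GROWTH_HORMONE_DECOY = OBO + "CHEBI_37845"
CHEM_ROOT = OBO + "CHEBI_24431"          # chemical entity
CHEM_MID = OBO + "CHEBI_23367"           # molecular entity

BETA_DISPOSITION = "non-activating competitive beta-adrenergic receptor binding disposition"
PPI_DISPOSITION = ("function-inhibiting hydrogen/potassium adenosine triphosphatase "
                   "enzyme (H+/K+ ATPase) binding disposition")
LTYPE_DISPOSITION = "function-inhibiting L-type voltage-gated calcium channel binding disposition"
VITK_DISPOSITION = "function-inhibiting vitamin K epoxide reductase binding disposition"
NKCC2_DISPOSITION = "function-inhibiting Na-K-Cl cotransporter 2 (NKCC2) binding disposition"
TTYPE_DISPOSITION = "function-inhibiting T-type calcium channel binding disposition"


class InfeasibleConfigError(Exception):
    """The requested fixture conditions cannot be realised.

    Deliberately not a ValueError: the config model raises it from its own
    validator and it must surface as-is rather than be collected into a
    validation report.
    """


class FixtureConfig(BaseModel):
    """Study conditions for one synthetic series."""

    seed: int = 0
    n_ingredients: int = Field(default=12, ge=0)
    n_cdfs: int = Field(default=8, ge=0)
    n_cds: int = Field(default=20, ge=0)
    n_bds: int = Field(default=8, ge=0)
    n_ndcs: int = Field(default=40, ge=0)
    n_releases: int = Field(default=5, ge=1)
    n_merges: int = Field(default=3, ge=0)
    n_splits: int = Field(default=1, ge=0)
    n_errors: int = Field(default=1, ge=0)
    n_silent_disappearances: int = Field(default=1, ge=0)
    label_match_fraction: float = Field(default=0.5, ge=0.0, le=1.0)
    exact_synonym_fraction: float = Field(default=0.1, ge=0.0, le=1.0)
    related_synonym_fraction: float = Field(default=0.2, ge=0.0, le=1.0)
    include_worked_examples: bool = True

    @property
    def total_events(self) -> int:
        return self.n_merges + self.n_splits + self.n_errors + self.n_silent_disappearances

    @model_validator(mode="after")
    def _feasible(self) -> "FixtureConfig":
        if self.include_worked_examples and self.n_ingredients < 3:
            raise InfeasibleConfigError("worked examples need at least 3 ingredient slots")
        n_other = self.n_ingredients - (3 if self.include_worked_examples else 0)
        if int(self.label_match_fraction * n_other) < 3:
            raise InfeasibleConfigError(
                "need at least three label-matchable ingredients to designate role bearers")
        if (self.label_match_fraction + self.exact_synonym_fraction
                + self.related_synonym_fraction) > 1.0 + 1e-9:
            raise InfeasibleConfigError("match fractions must not exceed 1")
        if self.total_events and self.n_releases < 2:
            raise InfeasibleConfigError("events need at least two releases")
        # victims are distinct, and at least one stable concept must survive
        if self.total_events >= self.n_cds:
            raise InfeasibleConfigError("event counts must leave at least one stable concept")
        if self.n_cds and self.n_cdfs == 0:
            raise InfeasibleConfigError("clinical drugs need at least one drug form")
        if self.n_bds and self.n_cds == 0:
            raise InfeasibleConfigError("branded drugs need at least one clinical drug")
        if self.n_ndcs and not (self.n_cds or self.n_bds):
            raise InfeasibleConfigError("NDCs need a drug product to attach to")
        return self


@dataclass(frozen=True)
class Event:
    kind: str          # "merge" | "split" | "error" | "disappear"
    victim: str
    release: int
    survivor: str | None = None            # merges only
    successors: tuple[str, str] | None = None  # splits only


@dataclass
class FixturePlan:
    """Everything random, decided once; writers are pure functions of this."""
    config: FixtureConfig
    ingredients: list[tuple[str, str]] = field(default_factory=list)  # (rxcui, name)
    cdf_ingredients: dict[str, list[str]] = field(default_factory=dict)
    cdf_names: dict[str, str] = field(default_factory=dict)
    cd_parent: dict[str, str] = field(default_factory=dict)
    cd_names: dict[str, str] = field(default_factory=dict)
    bd_parent: dict[str, str] = field(default_factory=dict)
    bd_names: dict[str, str] = field(default_factory=dict)
    ndc_parent: dict[str, tuple[str, str]] = field(default_factory=dict)  # ndc -> (id, kind)
    events: list[Event] = field(default_factory=list)
    event_by_victim: dict[str, Event] = field(default_factory=dict)
    # lexical-match assignment: rxcui -> ("label"|"exact_synonym"|"related_synonym", class IRI)
    matches: dict[str, tuple[str, str]] = field(default_factory=dict)
    role_bearers: dict[str, str] = field(default_factory=dict)  # rxcui -> role IRI
    worked: dict[str, str] = field(default_factory=dict)  # name -> rxcui


def build_plan(config: FixtureConfig) -> FixturePlan:
    rng = random.Random(config.seed)
    plan = FixturePlan(config)

    names: list[str] = []
    if config.include_worked_examples:
        names += ["Furosemide", "Somatropin", "Ethosuximide"]
    names += [f"synthchem {i}" for i in range(config.n_ingredients - len(names))]
    plan.ingredients = [(str(_IN_BASE + i), n) for i, n in enumerate(names)]
    if config.include_worked_examples:
        plan.worked = {n.casefold(): rx for rx, n in plan.ingredients[:3]}

    # lexical-match assignment over the non-worked ingredients
    other = plan.ingredients[3:] if config.include_worked_examples else plan.ingredients[:]
    n_lm = int(config.label_match_fraction * len(other))
    n_es = int(config.exact_synonym_fraction * len(other))
    n_rs = int(config.related_synonym_fraction * len(other))
    chebi_serial = 9_500_000
    for i, (rxcui, _) in enumerate(other):
        if i < n_lm:
            ann = "label"
        elif i < n_lm + n_es:
            ann = "exact_synonym"
        elif i < n_lm + n_es + n_rs:
            ann = "related_synonym"
        else:
            continue
        plan.matches[rxcui] = (ann, f"{OBO}CHEBI_{chebi_serial + i}")
    if config.include_worked_examples:
        plan.matches[plan.worked["furosemide"]] = ("label", FUROSEMIDE_CHEBI)
        plan.matches[plan.worked["ethosuximide"]] = ("label", f"{OBO}CHEBI_{chebi_serial - 1}")

    # role designation: first three label-matched synthetic ingredients
    label_matched = [rx for rx, _ in other if plan.matches.get(rx, ("", ""))[0] == "label"]
    plan.role_bearers = {label_matched[0]: BETA_ROLE, label_matched[1]: PPI_ROLE,
                         label_matched[2]: CCB_ROLE}
    if config.include_worked_examples:
        # the trap: ethosuximide carries the coarse calcium-channel-blocker role
        plan.role_bearers[plan.worked["ethosuximide"]] = CCB_ROLE

    plan.cdf_names = {str(_CDF_BASE + i): f"synthform {i}" for i in range(config.n_cdfs)}
    ing_ids = [rx for rx, _ in plan.ingredients]
    for cdf in plan.cdf_names:
        k = min(len(ing_ids), rng.choice([1, 2]))
        plan.cdf_ingredients[cdf] = sorted(rng.sample(ing_ids, k)) if k else []

    cdf_ids = list(plan.cdf_names)
    plan.cd_names = {str(_CD_BASE + i): f"synthdrug {i}" for i in range(config.n_cds)}
    for cd in plan.cd_names:
        plan.cd_parent[cd] = rng.choice(cdf_ids)

    cd_ids = list(plan.cd_names)
    parent_pool = cd_ids[: max(1, len(cd_ids) // 3)] if config.n_bds else []
    plan.bd_names = {str(_BD_BASE + i): f"synthbrand {i}" for i in range(config.n_bds)}
    for bd in plan.bd_names:
        plan.bd_parent[bd] = rng.choice(parent_pool)

    # --- event schedule ---
    child_free = [cd for cd in cd_ids if cd not in set(plan.bd_parent.values())]
    non_merge = config.n_splits + config.n_errors + config.n_silent_disappearances
    if non_merge + config.n_merges > len(cd_ids) - 1:
        raise InfeasibleConfigError("not enough clinical drugs for the requested events")
    if non_merge > len(child_free):
        raise InfeasibleConfigError(
            "split/error/disappearance victims must have no branded children")

    cf_victims = rng.sample(child_free, min(len(child_free), non_merge + config.n_merges))
    victims_non_merge = cf_victims[:non_merge]
    merge_victims = list(cf_victims[non_merge:])
    # draw any shortfall (and, when possible, one branded-drug parent so the
    # re-parenting path is exercised) from the remaining concepts
    remaining = [cd for cd in cd_ids if cd not in set(cf_victims)]
    pool_extra = [cd for cd in remaining if cd in set(plan.bd_parent.values())]
    while len(merge_victims) < config.n_merges:
        pick_from = pool_extra or remaining
        pick = pick_from[0]
        merge_victims.append(pick)
        remaining.remove(pick)
        if pick in pool_extra:
            pool_extra.remove(pick)
    if (config.n_merges and pool_extra and len(remaining) > 1
            and merge_victims and all(v in child_free for v in merge_victims)):
        # swap one victim for a branded-drug parent to cover re-parenting
        merge_victims[0] = pool_extra[0]
        remaining.remove(pool_extra[0])

    all_victims = set(victims_non_merge) | set(merge_victims)
    stable = [cd for cd in cd_ids if cd not in all_victims]

    merge_events: list[tuple[str, int]] = sorted(
        ((v, rng.randint(2, config.n_releases)) for v in merge_victims),
        key=lambda t: (t[1], t[0]),
    )
    for i, (victim, release) in enumerate(merge_events):
        survivor = None
        later = [(v2, r2) for v2, r2 in merge_events[i + 1:] if r2 > release]
        if later and rng.random() < 0.5 and victim in child_free:
            survivor = later[0][0]  # chained re-retirement
        if survivor is None:
            survivor = rng.choice(stable)
        plan.events.append(Event("merge", victim, release, survivor=survivor))

    kinds = (["split"] * config.n_splits + ["error"] * config.n_errors
             + ["disappear"] * config.n_silent_disappearances)
    for kind, victim in zip(kinds, victims_non_merge):
        release = rng.randint(2, config.n_releases)
        successors = None
        if kind == "split":
            pool = [cd for cd in cd_ids if cd != victim and cd in stable]
            if len(pool) < 2:
                raise InfeasibleConfigError("splits need two stable successor concepts")
            successors = tuple(sorted(rng.sample(pool, 2)))
        plan.events.append(Event(kind, victim, release, successors=successors))

    plan.event_by_victim = {e.victim: e for e in plan.events}

    # --- NDC codes ---
    product_ids = [(cd, "CD") for cd in cd_ids] + [(bd, "BD") for bd in plan.bd_names]
    seen: set[str] = set()
    while len(seen) < config.n_ndcs:
        code = "".join(rng.choice("0123456789") for _ in range(11))
        if code not in seen:
            seen.add(code)
            plan.ndc_parent[code] = rng.choice(product_ids)
    return plan


# ---------------------------------------------------------------------------
# Plan interpretation (ground-truth bookkeeping)
# ---------------------------------------------------------------------------

def _terminal(plan: FixturePlan, ident: str) -> tuple[str, str | None]:
    """(kind, terminal) for an identifier, by following the event list."""
    ev = plan.event_by_victim.get(ident)
    if ev is None:
        return ("CURRENT", ident)
    if ev.kind == "error":
        return ("ERROR", None)
    if ev.kind == "split":
        return ("SPLIT", None)
    if ev.kind == "disappear":
        return ("ORPHANED", ident)
    kind, term = _terminal(plan, ev.survivor)  # merge
    if kind == "CURRENT":
        return ("MERGED", term)
    return (kind, term)


def _current_id(plan: FixturePlan, ident: str, release: int) -> str | None:
    """The identifier carrying *ident*'s information at *release*, or None."""
    while True:
        ev = plan.event_by_victim.get(ident)
        if ev is None or ev.release > release:
            return ident
        if ev.kind != "merge":
            return None
        ident = ev.survivor


def _alive_cds(plan: FixturePlan, release: int) -> list[str]:
    return [cd for cd in plan.cd_names
            if (e := plan.event_by_victim.get(cd)) is None or e.release > release]


# ---------------------------------------------------------------------------
# Series generation
# ---------------------------------------------------------------------------

def _snapshot_for_release(plan: FixturePlan, k: int) -> ReleaseSnapshot:
    version = ReleaseVersion(ordinal=k, label=f"SYN{k:02d}")
    atoms: set[Atom] = set()
    for rxcui, name in plan.ingredients:
        atoms.add(Atom(rxcui, "IN", name))
    for rxcui, name in plan.cdf_names.items():
        atoms.add(Atom(rxcui, "SCDF", name))
    alive = set(_alive_cds(plan, k))
    for rxcui in alive:
        atoms.add(Atom(rxcui, "SCD", plan.cd_names[rxcui]))
    for rxcui, name in plan.bd_names.items():
        atoms.add(Atom(rxcui, "SBD", name))

    retirements: set[RetirementRecord] = set()
    for ev in plan.events:
        if ev.release > k or ev.kind == "disappear":
            continue
        if ev.kind == "merge":
            retirements.add(RetirementRecord(ev.victim, ev.survivor, 1))
        elif ev.kind == "error":
            retirements.add(RetirementRecord(ev.victim, ev.victim, 1))
        elif ev.kind == "split":
            for succ in ev.successors:
                retirements.add(RetirementRecord(ev.victim, succ, 2))

    ndc_attrs: set[NdcAttribute] = set()
    for ndc, (parent, _kind) in plan.ndc_parent.items():
        cur = _current_id(plan, parent, k)
        if cur is not None:
            ndc_attrs.add(NdcAttribute(ndc, cur, version))

    rels: set[tuple[str, str, str]] = set()
    for cdf, ings in plan.cdf_ingredients.items():
        for ing in ings:
            rels.add((cdf, REL_HAS_INGREDIENT, ing))
    for cd in alive:
        rels.add((cd, REL_ISA, plan.cd_parent[cd]))
    for bd, parent in plan.bd_parent.items():
        cur = _current_id(plan, parent, k)
        if cur is not None:
            rels.add((bd, REL_TRADENAME_OF, cur))

    return ReleaseSnapshot(version=version, atoms=frozenset(atoms),
                           ndc_attributes=frozenset(ndc_attrs),
                           retirements=frozenset(retirements),
                           relationships=frozenset(rels))


def _append_decoys(release_dir: Path) -> None:
    """Rows the extractors must ignore: foreign-source and foreign-type."""
    def row(schema, **kw):
        cells = ["" for _ in schema]
        for key, value in kw.items():
            cells[schema.index(key)] = value
        return "|".join(cells) + "|\n"

    with (release_dir / "RXNCONSO.RRF").open("a", encoding="utf-8") as fh:
        fh.write(row(RXNCONSO_SCHEMA, rxcui="9999901", lat="ENG", ispref="Y",
                     sab=RXNORM_SAB, tty="BN", str="decoy brand name"))
        fh.write(row(RXNCONSO_SCHEMA, rxcui="9999902", lat="ENG", ispref="Y",
                     sab="MSH", tty="IN", str="decoy foreign-source ingredient"))
    with (release_dir / "RXNSAT.RRF").open("a", encoding="utf-8") as fh:
        fh.write(row(RXNSAT_SCHEMA, rxcui="9999903", atn=NDC_ATN, sab="MTHSPL",
                     atv="99999999999"))


def generate_series(
    config: FixtureConfig,
    out_dir: str | Path,
    plan: FixturePlan | None = None,
) -> tuple[list[Path], dict]:
    """Write the release directories and return them with the manifest."""
    plan = plan or build_plan(config)
    out_dir = Path(out_dir)
    dirs: list[Path] = []
    for k in range(1, config.n_releases + 1):
        release_dir = out_dir / f"release_{k:02d}"
        write_release(_snapshot_for_release(plan, k), release_dir)
        _append_decoys(release_dir)
        dirs.append(release_dir)
    manifest = build_manifest(plan)
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")
    return dirs, manifest


# ---------------------------------------------------------------------------
# Mini-ChEBI generation
# ---------------------------------------------------------------------------

def generate_mini_chebi(
    config: FixtureConfig,
    out_path: str | Path,
    plan: FixturePlan | None = None,
) -> Path:
    """Write the mini ChEBI-style OWL snapshot (RDF/XML) for *plan*."""
    plan = plan or build_plan(config)
    g = rdflib.Graph()
    g.bind("obo", OBO)
    g.bind("oboInOwl", "http://www.geneontology.org/formats/oboInOwl#")

    def cls(iri: str, label: str, parent: str | None = None) -> URIRef:
        ref = URIRef(iri)
        g.add((ref, RDF.type, OWL.Class))
        g.add((ref, RDFS.label, Literal(label)))
        if parent:
            g.add((ref, RDFS.subClassOf, URIRef(parent)))
        return ref

    cls(CHEM_ROOT, "chemical entity")
    cls(CHEM_MID, "molecular entity", CHEM_ROOT)
    cls(ROLE_ROOT, "role")
    cls(BETA_ROLE, "beta-adrenergic antagonist", ROLE_ROOT)
    sub_beta = cls(OBO + "CHEBI_9000001", "selective beta-adrenergic antagonist", BETA_ROLE)
    cls(PPI_ROLE, "proton pump inhibitor", ROLE_ROOT)
    cls(CCB_ROLE, "calcium channel blocker", ROLE_ROOT)
    decoy = cls(GROWTH_HORMONE_DECOY, "growth hormone", ROLE_ROOT)
    g.add((decoy, RELATED_SYN_IRI, Literal("Somatropin")))

    names = dict(plan.ingredients)

    def add_role(subject: URIRef, role_iri: str) -> None:
        # content-derived blank-node label keeps output byte-deterministic
        b = BNode("r" + hashlib.sha1(f"{subject}|{role_iri}".encode()).hexdigest()[:16])
        g.add((subject, RDFS.subClassOf, b))
        g.add((b, RDF.type, OWL.Restriction))
        g.add((b, OWL.onProperty, HAS_ROLE_IRI))
        g.add((b, OWL.someValuesFrom, URIRef(role_iri)))

    for i, (rxcui, (ann, iri)) in enumerate(sorted(plan.matches.items())):
        name = names[rxcui]
        if ann == "label":
            ref = cls(iri, name, CHEM_MID)
        else:
            ref = cls(iri, f"synthetic compound {i}", CHEM_MID)
            prop = EXACT_SYN_IRI if ann == "exact_synonym" else RELATED_SYN_IRI
            g.add((ref, prop, Literal(name)))
        role = plan.role_bearers.get(rxcui)
        if role is not None:
            # the designated beta-blocker links via a sub-role, exercising
            # descendant-aware role mining
            add_role(ref, str(sub_beta) if role == BETA_ROLE else role)
    # furosemide keeps a related synonym alias, as in real ChEBI
    if config.include_worked_examples:
        g.add((URIRef(FUROSEMIDE_CHEBI), RELATED_SYN_IRI, Literal("frusemide")))

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_bytes(g.serialize(format="xml", encoding="utf-8"))
    return out_path


# ---------------------------------------------------------------------------
# Ground-truth manifest
# ---------------------------------------------------------------------------

def build_manifest(plan: FixturePlan) -> dict:
    config = plan.config

    terminal_map: dict[str, dict] = {}
    all_ids = ([rx for rx, _ in plan.ingredients] + list(plan.cdf_names)
               + list(plan.cd_names) + list(plan.bd_names))
    for ident in all_ids:
        kind, term = _terminal(plan, ident)
        terminal_map[ident] = {"kind": kind, "terminal": term}

    # NDC observations, release by release
    pairs: dict[tuple[str, str], str] = {}
    for ndc, (parent, _kind) in plan.ndc_parent.items():
        for k in range(1, config.n_releases + 1):
            cur = _current_id(plan, parent, k)
            if cur is None:
                continue
            kind, _term = _terminal(plan, cur)
            status = {"CURRENT": "INCLUDED", "MERGED": "INCLUDED",
                      "ERROR": "EXCLUDED_ERROR", "SPLIT": "EXCLUDED_SPLIT",
                      "ORPHANED": "ORPHANED"}[kind]
            pairs[(ndc, cur)] = status
    status_counts = {"INCLUDED": 0, "EXCLUDED_ERROR": 0, "EXCLUDED_SPLIT": 0, "ORPHANED": 0}
    for status in pairs.values():
        status_counts[status] += 1

    included_pairs: dict[str, str] = {}
    orphaned_codes: list[str] = []
    packaged: dict[str, tuple[str, str]] = {}
    for ndc, (parent, kind0) in plan.ndc_parent.items():
        kind, term = _terminal(plan, parent)
        if kind in ("ERROR", "SPLIT"):
            continue
        included_pairs[ndc] = term
        packaged[ndc] = (term, kind0)
        if kind == "ORPHANED":
            orphaned_codes.append(ndc)

    n_matched = len(plan.matches)
    final_cds = config.n_cds - config.n_merges - config.n_splits - config.n_errors
    n_pro = 1 if config.include_worked_examples else 0  # somatropin via override
    entity_counts = {
        "ingredients": config.n_ingredients,
        "dispositions": 6,
        "cdfs": config.n_cdfs,
        "cds": final_cds,
        "bds": config.n_bds,
        "packaged": len(packaged),
    }
    module_counts = {
        "dron-full": 0,
        "dron-chebi": n_matched + (2 if n_matched else 0),  # + mid and root ancestors
        "dron-pro": 2 * n_pro,                              # protein + somatotropin
        "dron-rxnorm": (config.n_ingredients - n_matched - n_pro)
        + config.n_cdfs + final_cds + config.n_bds + len(packaged),
        "dron-upper": 13,
    }

    tally = {"label": 0, "exact_synonym": 0, "related_synonym": 0,
             "override": n_pro, "none": 0}
    for ann, _iri in plan.matches.values():
        tally[ann] += 1
    tally["none"] = config.n_ingredients - n_matched - n_pro

    # disposition links: mined from roles, minus the curated exclusion,
    # plus the shipped curated lists (matched by name)
    links: dict[str, list[str]] = {d: [] for d in (
        BETA_DISPOSITION, PPI_DISPOSITION, LTYPE_DISPOSITION,
        VITK_DISPOSITION, NKCC2_DISPOSITION, TTYPE_DISPOSITION)}
    role_to_disposition = {BETA_ROLE: BETA_DISPOSITION, PPI_ROLE: PPI_DISPOSITION,
                           CCB_ROLE: LTYPE_DISPOSITION}
    etho = plan.worked.get("ethosuximide")
    for rxcui, role in plan.role_bearers.items():
        disposition = role_to_disposition[role]
        if disposition == LTYPE_DISPOSITION and rxcui == etho:
            continue  # curated exclusion
        links[disposition].append(rxcui)
    if config.include_worked_examples:
        links[NKCC2_DISPOSITION].append(plan.worked["furosemide"])
        links[TTYPE_DISPOSITION].append(etho)
    links = {d: sorted(v) for d, v in links.items()}

    # designated query answers over the final entity graph
    def ndcs_for_ingredient(rxcui: str) -> list[str]:
        cdfs = {c for c, ings in plan.cdf_ingredients.items() if rxcui in ings}
        cds = {cd for cd in plan.cd_names
               if _terminal(plan, cd)[0] in ("CURRENT", "ORPHANED")
               and plan.cd_parent[cd] in cdfs}
        bds = {bd for bd, p in plan.bd_parent.items() if _terminal(plan, p)[1] in cds}
        return sorted(
            ndc for ndc, (term, kind) in packaged.items()
            if (kind == "CD" and term in cds) or (kind == "BD" and term in bds)
        )

    query_ingredients = []
    if config.include_worked_examples:
        query_ingredients.append(plan.worked["furosemide"])
    beta_bearer = next(rx for rx, role in plan.role_bearers.items() if role == BETA_ROLE)
    query_ingredients.append(beta_bearer)
    ingredient_queries = {rx: ndcs_for_ingredient(rx) for rx in query_ingredients}
    disposition_queries = {
        d: sorted(set().union(*[set(ndcs_for_ingredient(rx)) for rx in links[d]] or [set()]))
        for d in (BETA_DISPOSITION, NKCC2_DISPOSITION)
    }

    return {
        "config": config.model_dump(),
        "terminal_map": terminal_map,
        "ndc_pairs": {f"{ndc}|{rx}": status for (ndc, rx), status in pairs.items()},
        "status_counts": status_counts,
        "included_pairs": included_pairs,
        "orphaned_codes": sorted(orphaned_codes),
        "entity_counts": entity_counts,
        "module_counts": module_counts,
        "match_tally": tally,
        "disposition_links": links,
        "queries": {"ingredient": ingredient_queries, "disposition": disposition_queries},
        "unattachable": 0,
    }


# ---------------------------------------------------------------------------
# One-call fixture
# ---------------------------------------------------------------------------

@dataclass
class FixturePaths:
    release_dirs: list[Path]
    chebi_path: Path
    manifest_path: Path
    manifest: dict


def generate_fixture(config: FixtureConfig, out_dir: str | Path) -> FixturePaths:
    """Generate the full fixture: release series, mini-ChEBI, manifest."""
    out_dir = Path(out_dir)
    plan = build_plan(config)
    dirs, manifest = generate_series(config, out_dir, plan)
    chebi = generate_mini_chebi(config, out_dir / "mini_chebi.owl", plan)
    return FixturePaths(dirs, chebi, out_dir / "manifest.json", manifest)
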