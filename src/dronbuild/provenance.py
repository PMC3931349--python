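"""Identifier provenance across a release series.

Drug-concept identifiers are retired over time: two identifiers naming the
same product are merged (one survives, or both retire into a fresh one),
identifiers entered in error are withdrawn, and occasionally one is split
into several successors.  A master conversion table maps every retired
identifier to the latest identifier naming the same entity, or to a status
code when no single successor exists:

* ``ERROR``    — entered in error (retired-record with ``cui1 == cui2``);
* ``S_RXNCUI`` — split into multiple successors (cardinality > 1);
* orphaned     — vanished from the concept file with no retirement record
  at all; the identifier is kept as a flagged self-reference so data
  attached to it stays reachable.

The table is maintained incrementally, release by release, in three steps:
detect identifiers that disappeared from the concept file, fill in their
successors from the retired-identifier records, then compact chains by
transitive closure so every entry points directly at its terminal
identifier (or inherits the terminal status of its chain).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

from .rrf_io import ReleaseSnapshot, RetirementRecord

logger = logging.getLogger(__name__)

#: Status codes stored literally in the persisted two-column table.
ERROR_CODE = "ERROR"
SPLIT_CODE = "S_RXNCUI"
_STATUS_CODES = frozenset({ERROR_CODE, SPLIT_CODE})


class ResolutionKind(Enum):
    CURRENT = "CURRENT"
    MERGED = "MERGED"
    ERROR = "ERROR"
    SPLIT = "SPLIT"
    ORPHANED = "ORPHANED"


@dataclass(frozen=True)
class Resolution:
    """Outcome of resolving one identifier.

    ``terminal`` is present for CURRENT / MERGED / ORPHANED resolutions and
    absent for ERROR / SPLIT, which have no single successor.
    """
    kind: ResolutionKind
    terminal: str | None = None

    def __post_init__(self) -> None:
        has_terminal = self.terminal is not None
        needs_terminal = self.kind in (
            ResolutionKind.CURRENT, ResolutionKind.MERGED, ResolutionKind.ORPHANED
        )
        if has_terminal != needs_terminal:
            raise ValueError(f"Resolution({self.kind}) terminal mismatch")


class ProvenanceCycleError(RuntimeError):
    """A retirement chain loops back on itself; the series is inconsistent."""

    def __init__(self, cycle: list[str]):
        self.cycle = cycle
        super().__init__("retirement cycle detected: " + " -> ".join(cycle + cycle[:1]))


class ConflictingRetirementError(ValueError):
    """One identifier carries both a merge record and a split record."""


@dataclass
class ProvenanceTable:
    """The master conversion table (old identifier -> successor or status).

    ``entries`` maps each retired identifier to its successor identifier or
    to one of the literal status codes.  ``orphaned`` flags entries that are
    self-references standing in for an undocumented disappearance.
    ``observed_current`` is the identifier set of the most recent release.
    """
    entries: dict[str, str] = field(default_factory=dict)
    orphaned: set[str] = field(default_factory=set)
    observed_current: set[str] = field(default_factory=set)
    compacted: bool = False

    def keys(self) -> set[str]:
        return set(self.entries)


# ---------------------------------------------------------------------------
# Step 1: disappearance detection
# ---------------------------------------------------------------------------

def detect_retired(
    registry_identifiers: set[str],
    current_snapshot: ReleaseSnapshot,
) -> set[str]:
    """Identifiers known from prior releases but absent from this one.

    The concept file lists every current identifier, so anything
    accumulated before that is no longer present must have been retired.
    """
    return set(registry_identifiers) - current_snapshot.atom_rxcuis()


# ---------------------------------------------------------------------------
# Step 2: successor assignment from retirement records
# ---------------------------------------------------------------------------

def apply_retirements(
    table: ProvenanceTable,
    records: set[RetirementRecord] | frozenset[RetirementRecord],
) -> ProvenanceTable:
    """Fill in successors for retired identifiers from the curated records.

    For each table key with a record: ``cui1 == cui2`` marks it ERROR;
    cardinality > 1 marks it split; cardinality 1 merges it into ``cui2``.
    Keys with no record remain flagged orphaned self-references.  Mutates
    and returns *table* (invalidating any earlier compaction).
    """
    by_cui1: dict[str, list[RetirementRecord]] = {}
    for rec in records:
        by_cui1.setdefault(rec.cui1, []).append(rec)

    for cui1, recs in by_cui1.items():
        if cui1 not in table.entries:
            continue  # record for an identifier we never tracked
        if table.entries[cui1] != cui1 or cui1 not in table.orphaned:
            # already assigned by an earlier release's records; records are
            # cumulative, so a repeat assignment is expected — keep the first
            continue
        errors = [r for r in recs if r.self_referential]
        splits = [r for r in recs if r.is_split and not r.self_referential]
        merges = [r for r in recs if not r.is_split and not r.self_referential]
        if merges and splits:
            raise ConflictingRetirementError(
                f"identifier {cui1} has both merge and split records: "
                f"{sorted((r.cui1, r.cui2, r.cardinality) for r in recs)}"
            )
        if errors:
            table.entries[cui1] = ERROR_CODE
        elif splits:
            table.entries[cui1] = SPLIT_CODE
        elif len(merges) == 1:
            table.entries[cui1] = merges[0].cui2
        else:  # several cardinality-1 records disagree
            raise ConflictingRetirementError(
                f"identifier {cui1} has multiple conflicting merge records: "
                f"{sorted(r.cui2 for r in merges)}"
            )
        table.orphaned.discard(cui1)
    table.compacted = False
    return table


def register_retired(table: ProvenanceTable, identifiers: set[str]) -> ProvenanceTable:
    """Add newly detected retirees as unresolved (orphaned self-reference)."""
    for ident in identifiers:
        if ident not in table.entries:
            table.entries[ident] = ident
            table.orphaned.add(ident)
    if identifiers:
        table.compacted = False
    return table


def reactivate(table: ProvenanceTable, current_ids: set[str]) -> set[str]:
    """Drop table keys that reappear in the current release.

    An identifier that vanishes and later returns is treated as current
    again; the stale entry is removed and the event logged.
    """
    returned = table.keys() & current_ids
    for ident in returned:
        logger.info("identifier %s reappeared in a newer release; treating as current", ident)
        del table.entries[ident]
        table.orphaned.discard(ident)
    if returned:
        table.compacted = False
    return returned


# ---------------------------------------------------------------------------
# Step 3: transitive closure
# ---------------------------------------------------------------------------

def compact_closure(table: ProvenanceTable) -> ProvenanceTable:
    """Point every entry directly at its chain's terminal value.

    A chain ends at a status code (ERROR / split), at an identifier in the
    current release, at a flagged orphan, or at an identifier never tracked
    (logged, treated as an orphaned endpoint).  Chains with a loop raise
    :class:`ProvenanceCycleError` listing the cycle.  Mutates and returns
    *table*; the operation is idempotent.
    """
    resolved: dict[str, str] = {}

    def terminal_of(start: str) -> str:
        path: list[str] = []
        on_path: set[str] = set()
        node = start
        while True:
            if node in resolved:
                end = resolved[node]
                break
            if node in on_path:
                raise ProvenanceCycleError(path[path.index(node):])
            value = table.entries.get(node)
            if value in _STATUS_CODES:
                end = value
                break
            if node in table.orphaned or value is None or value == node:
                if value is None and node not in table.observed_current:
                    logger.warning(
                        "chain from %s ends at untracked identifier %s; flagging orphaned",
                        start, node,
                    )
                    table.entries[node] = node
                    table.orphaned.add(node)
                end = node
                break
            if value in table.observed_current:
                end = value
                break
            path.append(node)
            on_path.add(node)
            node = value
        for seen in path:
            resolved[seen] = end
        resolved[start] = end
        return end

    for key in list(table.entries):
        if key in table.orphaned:
            continue
        end = terminal_of(key)
        table.entries[key] = end
    table.compacted = True
    return table


def resolve(identifier: str, table: ProvenanceTable) -> Resolution:
    """Resolve an identifier to its terminal form or status.

    Requires a compacted table.  Identifiers in the current release resolve
    to themselves; unknown identifiers are assumed current (logged), since
    the files are not referentially closed.
    """
    if not table.compacted:
        raise ValueError("provenance table must be compacted before resolving")
    if identifier in table.observed_current:
        return Resolution(ResolutionKind.CURRENT, identifier)
    value = table.entries.get(identifier)
    if value is None:
        logger.warning("unknown identifier %s; treating as current", identifier)
        return Resolution(ResolutionKind.CURRENT, identifier)
    if value == ERROR_CODE:
        return Resolution(ResolutionKind.ERROR)
    if value == SPLIT_CODE:
        return Resolution(ResolutionKind.SPLIT)
    if value in table.orphaned or (value == identifier and identifier in table.orphaned):
        return Resolution(ResolutionKind.ORPHANED, value)
    if value in table.observed_current:
        return Resolution(ResolutionKind.MERGED, value)
    # compacted chains end at current, orphaned, or status values only;
    # anything else would be a compaction bug
    raise AssertionError(f"compacted entry {identifier} -> {value} has no terminal class")


def update_for_release(
    table: ProvenanceTable,
    known_identifiers: set[str],
    snapshot: ReleaseSnapshot,
) -> ProvenanceTable:
    """Run the per-release maintenance procedure (steps 1–2 plus bookkeeping).

    Reactivates returned identifiers, records this release's identifier set
    as current, registers disappearances, and applies the release's
    retirement records.  Compaction (step 3) is run once after the last
    release, or on demand.
    """
    current = set(snapshot.atom_rxcuis())
    reactivate(table, current)
    table.observed_current = current
    newly_retired = detect_retired(known_identifiers, snapshot)
    register_retired(table, newly_retired)
    apply_retirements(table, snapshot.retirements)
    return table
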