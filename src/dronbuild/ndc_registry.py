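"""Comprehensive historical National Drug Code registry (the NDC_COMP table).

Each release of an RxNorm-format series carries only the currently active
NDCs, so a historically complete code list must be accumulated across the
whole series.  Every (NDC, identifier) observation ever made is kept, with
the release span over which it was seen; nothing is deleted.  After the
provenance table is compacted, each observation is resolved to a status:

* ``INCLUDED``       — resolves to a current (or merged-into-current) identifier;
* ``EXCLUDED_ERROR`` — the identifier was entered in error; the code is kept
  in the registry for audit but emitted nowhere downstream;
* ``EXCLUDED_SPLIT`` — the identifier was split and the code cannot be
  attributed to a single successor without manual curation;
* ``ORPHANED``       — the identifier vanished with no retirement record;
  the code is retained under the last known identifier and flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

from .provenance import ProvenanceTable, ResolutionKind, resolve
from .rrf_io import ReleaseSnapshot, ReleaseVersion

logger = logging.getLogger(__name__)


class NdcStatus(Enum):
    INCLUDED = "INCLUDED"
    EXCLUDED_ERROR = "EXCLUDED_ERROR"
    EXCLUDED_SPLIT = "EXCLUDED_SPLIT"
    ORPHANED = "ORPHANED"


@dataclass
class NdcEntry:
    """One (NDC, identifier-at-observation) pair and its release span."""
    ndc: str
    original_rxcui: str
    first_seen: ReleaseVersion
    last_seen: ReleaseVersion
    resolved_rxcui: str | None = None
    status: NdcStatus | None = None

    def __post_init__(self) -> None:
        if self.first_seen > self.last_seen:
            raise ValueError("first_seen must not be after last_seen")


@dataclass
class NdcRegistry:
    """Accumulated NDC observations, one entry per (ndc, original_rxcui)."""
    entries: dict[tuple[str, str], NdcEntry] = field(default_factory=dict)
    finalized: bool = False

    def __len__(self) -> int:
        return len(self.entries)

    def identifiers(self) -> set[str]:
        return {e.original_rxcui for e in self.entries.values()}

    def status_counts(self) -> dict[str, int]:
        counts = {s.value: 0 for s in NdcStatus}
        for e in self.entries.values():
            if e.status is not None:
                counts[e.status.value] += 1
        return counts


def accumulate(registry: NdcRegistry, snapshot: ReleaseSnapshot) -> NdcRegistry:
    """Upsert this release's NDC observations into the registry.

    A new (ndc, rxcui) pair opens an entry with a one-release span; a
    repeat observation extends ``last_seen``.  Entries are never removed,
    so the registry only grows across the series.
    """
    for attr in snapshot.ndc_attributes:
        key = (attr.ndc, attr.rxcui)
        entry = registry.entries.get(key)
        if entry is None:
            registry.entries[key] = NdcEntry(
                ndc=attr.ndc, original_rxcui=attr.rxcui,
                first_seen=snapshot.version, last_seen=snapshot.version,
            )
        elif snapshot.version > entry.last_seen:
            entry.last_seen = snapshot.version
    return registry


def finalize(registry: NdcRegistry, table: ProvenanceTable) -> NdcRegistry:
    """Resolve every entry through the compacted provenance table.

    ERROR identifiers exclude their codes; split identifiers likewise
    (successor attribution would need manual curation).  Merged and current
    identifiers include the code under the terminal identifier; silently
    vanished identifiers keep the code flagged orphaned.
    """
    for entry in registry.entries.values():
        res = resolve(entry.original_rxcui, table)
        if res.kind is ResolutionKind.ERROR:
            entry.status = NdcStatus.EXCLUDED_ERROR
            entry.resolved_rxcui = None
        elif res.kind is ResolutionKind.SPLIT:
            entry.status = NdcStatus.EXCLUDED_SPLIT
            entry.resolved_rxcui = None
        elif res.kind is ResolutionKind.ORPHANED:
            entry.status = NdcStatus.ORPHANED
            entry.resolved_rxcui = res.terminal
        else:  # CURRENT or MERGED
            entry.status = NdcStatus.INCLUDED
            entry.resolved_rxcui = res.terminal
    registry.finalized = True
    return registry


def included_ndcs(registry: NdcRegistry) -> set[tuple[str, str]]:
    """The deduplicated (ndc, resolved identifier) pairs fed downstream.

    INCLUDED and ORPHANED entries qualify.  When one code's entries resolve
    to different identifiers, the observation with the latest ``last_seen``
    wins and the losers are logged for audit (a code legitimately reused
    across products keeps only its most recent assignment).
    """
    if not registry.finalized:
        raise ValueError("registry must be finalized before listing included codes")
    best: dict[str, NdcEntry] = {}
    for entry in registry.entries.values():
        if entry.status not in (NdcStatus.INCLUDED, NdcStatus.ORPHANED):
            continue
        prev = best.get(entry.ndc)
        if prev is None:
            best[entry.ndc] = entry
            continue
        if prev.resolved_rxcui == entry.resolved_rxcui:
            # same terminal identifier observed under different originals:
            # keep the longer-lived span for bookkeeping, no conflict
            if entry.last_seen > prev.last_seen:
                best[entry.ndc] = entry
            continue
        winner, loser = (entry, prev) if (entry.last_seen, entry.resolved_rxcui) > \
            (prev.last_seen, prev.resolved_rxcui) else (prev, entry)
        logger.info(
            "NDC %s resolves to both %s and %s; keeping latest-seen %s",
            entry.ndc, prev.resolved_rxcui, entry.resolved_rxcui, winner.resolved_rxcui,
        )
        best[entry.ndc] = winner
    return {(e.ndc, e.resolved_rxcui) for e in best.values()}  # type: ignore[misc]


def orphaned_ndcs(registry: NdcRegistry) -> set[str]:
    """Codes whose winning entry is flagged orphaned (for downstream flags)."""
    if not registry.finalized:
        raise ValueError("registry must be finalized first")
    pairs = included_ndcs(registry)
    orphan_terminals = {
        e.resolved_rxcui for e in registry.entries.values()
        if e.status is NdcStatus.ORPHANED
    }
    return {ndc for ndc, rxcui in pairs if rxcui in orphan_terminals}
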