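"""Deprecated-identifier tracking: detection, successor assignment, closure."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dronbuild.provenance import (
    ERROR_CODE,
    SPLIT_CODE,
    ConflictingRetirementError,
    ProvenanceCycleError,
    ProvenanceTable,
    ResolutionKind,
    apply_retirements,
    compact_closure,
    detect_retired,
    register_retired,
    resolve,
    update_for_release,
)
from dronbuild.rrf_io import (
    Atom,
    ReleaseSnapshot,
    ReleaseVersion,
    RetirementRecord,
)


def snap(ordinal, rxcuis, retirements=()):
    return ReleaseSnapshot(
        version=ReleaseVersion(ordinal, f"v{ordinal}"),
        atoms=frozenset(Atom(r, "SCD", f"drug {r}") for r in rxcuis),
        ndc_attributes=frozenset(),
        retirements=frozenset(RetirementRecord(*r) for r in retirements),
    )


def make_table(entries=None, orphaned=(), current=(), compact=False):
    t = ProvenanceTable(entries=dict(entries or {}), orphaned=set(orphaned),
                        observed_current=set(current))
    return compact_closure(t) if compact else t


class TestDetectRetired:
    def test_set_difference(self):
        assert detect_retired({"A", "B", "C"}, snap(2, {"A", "C"})) == {"B"}

    def test_registry_subset_of_snapshot(self):
        assert detect_retired({"A"}, snap(2, {"A", "B"})) == set()

    def test_mass_disappearance_without_records_yields_orphan_candidates(self):
        registry = {str(i) for i in range(40)}
        missing = detect_retired(registry, snap(2, set()))
        assert missing == registry
        table = register_retired(ProvenanceTable(), missing)
        assert table.orphaned == registry


class TestApplyRetirements:
    def test_self_referential_record_marks_error(self):
        t = make_table({"100": "100"}, orphaned={"100"})
        apply_retirements(t, {RetirementRecord("100", "100", 1)})
        assert t.entries["100"] == ERROR_CODE

    def test_cardinality_above_one_marks_split(self):
        t = make_table({"100": "100"}, orphaned={"100"})
        apply_retirements(t, {RetirementRecord("100", "201", 2),
                              RetirementRecord("100", "202", 2)})
        assert t.entries["100"] == SPLIT_CODE

    def test_cardinality_one_merges(self):
        t = make_table({"100": "100"}, orphaned={"100"})
        apply_retirements(t, {RetirementRecord("100", "200", 1)})
        assert t.entries["100"] == "200"
        assert "100" not in t.orphaned

    def test_conflicting_merge_and_split_records_rejected(self):
        t = make_table({"100": "100"}, orphaned={"100"})
        with pytest.raises(ConflictingRetirementError):
            apply_retirements(t, {RetirementRecord("100", "200", 1),
                                  RetirementRecord("100", "201", 2)})

    def test_keys_without_records_stay_orphaned(self):
        t = make_table({"100": "100"}, orphaned={"100"})
        apply_retirements(t, {RetirementRecord("999", "998", 1)})
        assert t.orphaned == {"100"}


class TestCompactClosure:
    def test_two_step_chain_points_at_terminal(self):
        t = make_table({"A": "B", "B": "C"}, current={"C"}, compact=True)
        assert t.entries == {"A": "C", "B": "C"}

    def test_error_absorbs_chain(self):
        t = make_table({"A": "B", "B": ERROR_CODE}, compact=True)
        assert t.entries["A"] == ERROR_CODE

    def test_cycle_is_a_hard_error(self):
        with pytest.raises(ProvenanceCycleError) as exc:
            make_table({"A": "B", "B": "A"}, compact=True)
        assert set(exc.value.cycle) == {"A", "B"}

    def test_chain_into_orphan_keeps_orphan_terminal(self):
        t = make_table({"A": "B", "B": "B"}, orphaned={"B"}, compact=True)
        assert resolve("A", t) .kind is ResolutionKind.ORPHANED
        assert resolve("A", t).terminal == "B"


class TestResolve:
    def test_current_identifier_resolves_to_itself(self):
        t = make_table(current={"X"}, compact=True)
        r = resolve("X", t)
        assert (r.kind, r.terminal) == (ResolutionKind.CURRENT, "X")

    def test_merged_identifier_carries_terminal(self):
        t = make_table({"A": "C"}, current={"C"}, compact=True)
        r = resolve("A", t)
        assert (r.kind, r.terminal) == (ResolutionKind.MERGED, "C")

    def test_split_resolution_has_no_terminal(self):
        t = make_table({"A": SPLIT_CODE}, compact=True)
        r = resolve("A", t)
        assert (r.kind, r.terminal) == (ResolutionKind.SPLIT, None)

    def test_unknown_identifier_assumed_current(self):
        t = make_table(current={"X"}, compact=True)
        assert resolve("Z", t).kind is ResolutionKind.CURRENT


# ---------------------------------------------------------------------------
# Properties over random acyclic chain structures
# ---------------------------------------------------------------------------

@st.composite
def chain_tables(draw):
    """Random acyclic successor structures with current/status endpoints."""
    n = draw(st.integers(2, 12))
    ids = [f"c{i}" for i in range(n)]
    entries, orphaned, current = {}, set(), set()
    for i, ident in enumerate(ids):
        fate = draw(st.sampled_from(["current", "merge", "error", "split", "orphan"]))
        if fate == "current" or (fate == "merge" and i == n - 1):
            current.add(ident)
        elif fate == "merge":
            entries[ident] = draw(st.sampled_from(ids[i + 1:]))  # forward edge: acyclic
        elif fate == "error":
            entries[ident] = ERROR_CODE
        elif fate == "split":
            entries[ident] = SPLIT_CODE
        else:
            entries[ident] = ident
            orphaned.add(ident)
    return ProvenanceTable(entries=entries, orphaned=orphaned, observed_current=current)


def naive_terminal(table, ident):
    """Independent chain-following oracle (no memoisation, no mutation)."""
    seen = set()
    node = ident
    while True:
        assert node not in seen, "oracle hit a cycle"
        seen.add(node)
        if node in table.observed_current and node != ident:
            return ("MERGED", node)
        value = table.entries.get(node)
        if value == ERROR_CODE:
            return ("ERROR", None)
        if value == SPLIT_CODE:
            return ("SPLIT", None)
        if node in table.orphaned:
            return (("ORPHANED", node) if node != ident else ("ORPHANED", node))
        if value is None:
            return (("CURRENT", node) if node == ident else ("MERGED", node))
        node = value


@settings(max_examples=60, deadline=None)
@given(chain_tables())
def test_closure_matches_chain_following_oracle(table):
    snapshot = dict(table.entries)
    compact_closure(table)
    for ident in snapshot:
        kind, term = naive_terminal(
            ProvenanceTable(entries=snapshot, orphaned=set(table.orphaned),
                            observed_current=set(table.observed_current)), ident)
        r = resolve(ident, table)
        assert r.kind.value == kind
        assert r.terminal == term


@settings(max_examples=60, deadline=None)
@given(chain_tables())
def test_compact_closure_is_idempotent(table):
    compact_closure(table)
    once = dict(table.entries)
    compact_closure(table)
    assert table.entries == once


@settings(max_examples=60, deadline=None)
@given(chain_tables())
def test_terminal_of_merged_resolution_is_fixed_point(table):
    compact_closure(table)
    for ident in list(table.entries):
        r = resolve(ident, table)
        if r.kind in (ResolutionKind.MERGED, ResolutionKind.CURRENT):
            again = resolve(r.terminal, table)
            assert again.terminal == r.terminal


def test_status_absorption_through_long_chains():
    for code, kind in ((ERROR_CODE, ResolutionKind.ERROR), (SPLIT_CODE, ResolutionKind.SPLIT)):
        entries = {f"n{i}": f"n{i+1}" for i in range(10)}
        entries["n10"] = code
        t = make_table(entries, compact=True)
        assert resolve("n0", t).kind is kind


def test_no_key_maps_to_itself_unless_orphaned():
    t = make_table({"A": "B", "B": "C"}, current={"C"}, compact=True)
    for key, value in t.entries.items():
        assert key != value or key in t.orphaned


class TestIncrementalVersusScratch:
    def test_incremental_series_equals_single_pass_oracle(self):
        """Per-release maintenance ends at the same table as a from-scratch pass."""
        releases = [
            snap(1, {"A", "B", "C", "D", "E"}),
            snap(2, {"B", "C", "D", "E"}, [("A", "B", 1)]),
            snap(3, {"C", "D", "E"}, [("A", "B", 1), ("B", "C", 1)]),
            snap(4, {"C", "E"}, [("A", "B", 1), ("B", "C", 1), ("D", "D", 1)]),
        ]
        table = ProvenanceTable()
        known = set()
        for s in releases:
            update_for_release(table, known, s)
            known |= s.atom_rxcuis()
        compact_closure(table)

        # scratch oracle: all identifiers ever, minus the last release's,
        # chained through the union of all retirement records
        all_ids = set().union(*[s.atom_rxcuis() for s in releases])
        final = releases[-1].atom_rxcuis()
        records = {}
        for s in releases:
            for rec in s.retirements:
                records.setdefault(rec.cui1, rec)
        for ident in sorted(all_ids - final):
            rec = records.get(ident)
            node, status = ident, None
            while rec is not None:
                if rec.self_referential:
                    status = "ERROR"
                    break
                if rec.is_split:
                    status = "SPLIT"
                    break
                node = rec.cui2
                rec = records.get(node) if node not in final else None
            r = resolve(ident, table)
            if status:
                assert r.kind.value == status
            elif node in final:
                assert (r.kind, r.terminal) == (ResolutionKind.MERGED, node)
            else:
                assert (r.kind, r.terminal) == (ResolutionKind.ORPHANED, node)

    def test_reappearing_identifier_is_current_again(self):
        releases = [snap(1, {"A", "B"}), snap(2, {"B"}), snap(3, {"A", "B"})]
        table = ProvenanceTable()
        known = set()
        for s in releases:
            update_for_release(table, known, s)
            known |= s.atom_rxcuis()
        compact_closure(table)
        assert resolve("A", table).kind is ResolutionKind.CURRENT
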