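"""Reading and writing the Rich Release Format (RRF) dialect.

RxNorm releases ship as pipe-delimited ``.RRF`` files: one record per line,
a trailing ``|`` after the last field, no quoting or escaping, UTF-8.  Only
the files the build pipeline consumes are modelled here:

* ``RXNCONSO.RRF`` — concept names and term types (atoms),
* ``RXNSAT.RRF``   — concept attributes, from which NDCs are mined,
* ``RXNCUI.RRF``   — retired-identifier records with merge/split cardinality,
* ``RXNCUICHANGES.RRF`` — identifier-change log (parsed and logged only),
* ``RXNSAB.RRF``   — source metadata, from which the release version is read,
* ``RXNREL.RRF``   — inter-concept relationships (optional input).

Column layouts follow the public RxNorm technical documentation; the
extractors project out exactly the fields the build needs and apply the
source/term-type filters so that only RxNorm-curated content flows
downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Column schemas (public RxNorm RRF layouts) and filter constants
# ---------------------------------------------------------------------------

RXNCONSO_SCHEMA: tuple[str, ...] = (
    "rxcui", "lat", "ts", "lui", "stt", "sui", "ispref", "rxaui", "saui",
    "scui", "sdui", "sab", "tty", "code", "str", "srl", "suppress", "cvf",
)

RXNSAT_SCHEMA: tuple[str, ...] = (
    "rxcui", "lui", "sui", "rxaui", "stype", "code", "atui", "satui",
    "atn", "sab", "atv", "suppress", "cvf",
)

RXNCUI_SCHEMA: tuple[str, ...] = (
    "cui1", "ver_start", "ver_end", "cardinality", "cui2",
)

RXNCUICHANGES_SCHEMA: tuple[str, ...] = (
    "rxaui", "code", "sab", "tty", "str", "rxcui",
)

RXNSAB_SCHEMA: tuple[str, ...] = (
    "vcui", "rcui", "vsab", "rsab", "son", "sf", "sver", "vstart", "vend",
    "imeta", "rmeta", "slc", "scc", "srl", "tfr", "cfr", "cxty", "ttyl",
    "atnl", "lat", "cenc", "curver", "sabin", "ssn", "scit",
)

RXNREL_SCHEMA: tuple[str, ...] = (
    "rxcui1", "rxaui1", "stype1", "rel", "rxcui2", "rxaui2", "stype2",
    "rela", "rui", "srui", "sab", "sl", "dir", "rg", "suppress", "cvf",
)

#: Source abbreviation for content curated within RxNorm itself.
RXNORM_SAB = "RXNORM"

#: Attribute name under which NDC codes are stored in RXNSAT.
NDC_ATN = "NDC"

#: The four term types the build keeps (drug-product and ingredient atoms).
PRODUCT_TTYS = frozenset({"SCDF", "SCD", "SBD", "IN"})

#: Relationship labels consumed by the entity-graph builder.
REL_ISA = "isa"                    # SCD -> SCDF
REL_HAS_INGREDIENT = "has_ingredient"  # SCDF (or SCD) -> IN
REL_TRADENAME_OF = "tradename_of"      # SBD -> SCD
ENTITY_RELAS = frozenset({REL_ISA, REL_HAS_INGREDIENT, REL_TRADENAME_OF})


class RrfParseError(ValueError):
    """A malformed line or file in the RRF dialect."""


class RrfMissingFileError(FileNotFoundError):
    """An expected RRF file is absent from the release directory."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class ReleaseVersion:
    """One release in the chronological series.

    ``label`` is the opaque version string from the source-metadata file;
    ``ordinal`` is the release's position in the series (strictly increasing,
    assigned by the caller that enumerates release directories).
    """
    ordinal: int
    label: str


@dataclass(frozen=True)
class Atom:
    """A kept concept row: identifier, term type and normalized name."""
    rxcui: str
    tty: str
    name: str

    def __post_init__(self) -> None:
        if not self.rxcui:
            raise ValueError("Atom.rxcui must be non-empty")
        if self.tty not in PRODUCT_TTYS:
            raise ValueError(f"Atom.tty must be one of {sorted(PRODUCT_TTYS)}, got {self.tty!r}")


@dataclass(frozen=True)
class NdcAttribute:
    """An RxNorm-curated NDC observed on a concept in one release."""
    ndc: str
    rxcui: str
    release: ReleaseVersion

    def __post_init__(self) -> None:
        if not self.ndc:
            raise ValueError("NdcAttribute.ndc must be non-empty")


@dataclass(frozen=True)
class RetirementRecord:
    """One retired-identifier row: ``cui1`` retired into ``cui2``.

    ``cui1 == cui2`` marks an identifier entered in error; a cardinality
    greater than one marks a split into multiple successors.
    """
    cui1: str
    cui2: str
    cardinality: int

    def __post_init__(self) -> None:
        if not self.cui1:
            raise ValueError("RetirementRecord.cui1 must be non-empty")
        if self.cardinality < 1:
            raise ValueError("RetirementRecord.cardinality must be >= 1")

    @property
    def self_referential(self) -> bool:
        """True when the record marks an identifier entered in error."""
        return self.cui1 == self.cui2

    @property
    def is_split(self) -> bool:
        return self.cardinality > 1


@dataclass(frozen=True)
class ReleaseSnapshot:
    """Parsed content of one release: exactly the fields the build uses.

    RRF files are not referentially closed — identifiers referenced by NDC
    attributes or relationships need not appear among the atoms; such rows
    are tolerated and logged downstream rather than rejected here.
    """
    version: ReleaseVersion
    atoms: frozenset[Atom]
    ndc_attributes: frozenset[NdcAttribute]
    retirements: frozenset[RetirementRecord]
    relationships: frozenset[tuple[str, str, str]] = field(default_factory=frozenset)

    def atom_rxcuis(self) -> frozenset[str]:
        return frozenset(a.rxcui for a in self.atoms)


# ---------------------------------------------------------------------------
# Low-level parsing
# ---------------------------------------------------------------------------

def parse_rrf_file(
    path: str | Path,
    schema: Sequence[str],
    strict: bool = True,
) -> list[dict[str, str]]:
    """Parse one pipe-delimited RRF file into row dicts keyed by *schema*.

    A trailing delimiter (empty final token) is permitted and dropped.
    Lines whose field count disagrees with the schema raise
    :class:`RrfParseError` naming the file and line (or are skipped with a
    warning when ``strict`` is false).  Blank lines are ignored.
    """
    path = Path(path)
    if not path.is_file():
        raise RrfMissingFileError(f"RRF file not found: {path}")
    rows: list[dict[str, str]] = []
    n = len(schema)
    with path.open("r", encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("|")
            if fields and fields[-1] == "":
                fields.pop()  # trailing delimiter
            if len(fields) != n:
                msg = (f"{path.name} line {lineno}: expected {n} fields, "
                       f"got {len(fields)}")
                if strict:
                    raise RrfParseError(msg)
                logger.warning("skipping malformed row: %s", msg)
                continue
            rows.append(dict(zip(schema, fields)))
    return rows


# ---------------------------------------------------------------------------
# Field extraction (the subset of each file the build consumes)
# ---------------------------------------------------------------------------

def extract_atoms(rows: Iterable[dict[str, str]]) -> set[Atom]:
    """Project concept-file rows to atoms.

    Keeps only rows curated within RxNorm (``sab == RXNORM``) whose term
    type is one of SCDF/SCD/SBD/IN.  One atom is kept per (rxcui, tty)
    pair; the name is taken from the preferred row (``ispref == 'Y'``),
    falling back to the first row in file order.  Conflicting names for a
    pair are logged and the first preferred name wins.
    """
    chosen: dict[tuple[str, str], tuple[str, bool]] = {}  # (rxcui,tty) -> (name, was_pref)
    for row in rows:
        if row.get("sab") != RXNORM_SAB or row.get("tty") not in PRODUCT_TTYS:
            continue
        key = (row["rxcui"], row["tty"])
        name = row.get("str", "")
        pref = row.get("ispref") == "Y"
        if key not in chosen:
            chosen[key] = (name, pref)
        else:
            prev_name, prev_pref = chosen[key]
            if pref and not prev_pref:
                chosen[key] = (name, True)
            elif pref == prev_pref and name != prev_name:
                logger.warning(
                    "conflicting names for rxcui=%s tty=%s: keeping %r, ignoring %r",
                    key[0], key[1], prev_name, name,
                )
    return {Atom(rxcui=k[0], tty=k[1], name=v[0]) for k, v in chosen.items()}


def extract_ndc_attributes(
    rows: Iterable[dict[str, str]],
    version: ReleaseVersion,
) -> set[NdcAttribute]:
    """Project attribute-file rows to NDC observations.

    Exactly the rows whose attribute name is ``NDC`` *and* whose source is
    RxNorm itself are kept (NDCs asserted by other UMLS sources, e.g.
    MTHSPL, are ignored), each tagged with the release *version*.
    """
    out: set[NdcAttribute] = set()
    for row in rows:
        if row.get("atn") == NDC_ATN and row.get("sab") == RXNORM_SAB:
            out.add(NdcAttribute(ndc=row["atv"], rxcui=row["rxcui"], release=version))
    return out


def extract_retirements(rows: Iterable[dict[str, str]]) -> set[RetirementRecord]:
    """Project retired-identifier rows to :class:`RetirementRecord`."""
    out: set[RetirementRecord] = set()
    for i, row in enumerate(rows, start=1):
        raw = row.get("cardinality", "")
        try:
            card = int(raw)
        except ValueError:
            raise RrfParseError(
                f"retired-identifier row {i}: cardinality {raw!r} is not an integer"
            ) from None
        if card < 1:
            raise RrfParseError(
                f"retired-identifier row {i}: cardinality must be positive, got {card}"
            )
        out.add(RetirementRecord(cui1=row["cui1"], cui2=row["cui2"], cardinality=card))
    return out


def extract_relationships(rows: Iterable[dict[str, str]]) -> set[tuple[str, str, str]]:
    """Project relationship rows to (rxcui1, rela, rxcui2) triples.

    Only RxNorm-curated rows with one of the relationship labels the
    entity-graph builder consumes are kept.
    """
    return {
        (row["rxcui1"], row["rela"], row["rxcui2"])
        for row in rows
        if row.get("sab") == RXNORM_SAB and row.get("rela") in ENTITY_RELAS
    }


def parse_version(rows: Iterable[dict[str, str]]) -> str:
    """Read the release version string from source-metadata rows.

    The metadata file must contain exactly one RxNorm source row; its
    ``sver`` field is the version label, captured verbatim.
    """
    rxnorm_rows = [r for r in rows if r.get("rsab") == RXNORM_SAB]
    if len(rxnorm_rows) != 1:
        raise RrfParseError(
            f"source-metadata file must contain exactly one {RXNORM_SAB} row, "
            f"found {len(rxnorm_rows)}"
        )
    return rxnorm_rows[0]["sver"]


# ---------------------------------------------------------------------------
# Release-directory reader and fixture writer
# ---------------------------------------------------------------------------

_FILES = {
    "RXNCONSO.RRF": RXNCONSO_SCHEMA,
    "RXNSAT.RRF": RXNSAT_SCHEMA,
    "RXNCUI.RRF": RXNCUI_SCHEMA,
    "RXNCUICHANGES.RRF": RXNCUICHANGES_SCHEMA,
    "RXNSAB.RRF": RXNSAB_SCHEMA,
}


def read_release(
    directory: str | Path,
    ordinal: int,
    strict: bool = True,
) -> ReleaseSnapshot:
    """Parse one release directory into a :class:`ReleaseSnapshot`.

    The five core files are required; the relationship file (RXNREL.RRF)
    is optional.  The identifier-change file is parsed for dialect
    validation and logged but contributes nothing further: the provenance
    mapping is derived from the retired-identifier file plus disappearance
    detection.
    """
    directory = Path(directory)
    version = ReleaseVersion(
        ordinal=ordinal,
        label=parse_version(parse_rrf_file(directory / "RXNSAB.RRF", RXNSAB_SCHEMA, strict)),
    )
    conso = parse_rrf_file(directory / "RXNCONSO.RRF", RXNCONSO_SCHEMA, strict)
    sat = parse_rrf_file(directory / "RXNSAT.RRF", RXNSAT_SCHEMA, strict)
    cui = parse_rrf_file(directory / "RXNCUI.RRF", RXNCUI_SCHEMA, strict)
    changes = parse_rrf_file(directory / "RXNCUICHANGES.RRF", RXNCUICHANGES_SCHEMA, strict)
    if changes:
        logger.info("%s: %d identifier-change rows parsed (informational only)",
                    directory.name, len(changes))
    rel_path = directory / "RXNREL.RRF"
    relationships: set[tuple[str, str, str]] = set()
    if rel_path.is_file():
        relationships = extract_relationships(parse_rrf_file(rel_path, RXNREL_SCHEMA, strict))
    return ReleaseSnapshot(
        version=version,
        atoms=frozenset(extract_atoms(conso)),
        ndc_attributes=frozenset(extract_ndc_attributes(sat, version)),
        retirements=frozenset(extract_retirements(cui)),
        relationships=frozenset(relationships),
    )


def _write_rrf(path: Path, schema: Sequence[str], rows: Iterable[Sequence[str]]) -> None:
    with path.open("w", encoding="utf-8", newline="") as fh:
        for row in rows:
            assert len(row) == len(schema)
            fh.write("|".join(row) + "|\n")


def write_release(snapshot: ReleaseSnapshot, directory: str | Path) -> Path:
    """Write a snapshot back out as a release directory in the RRF dialect.

    This is the fixture writer: re-parsing the directory with
    :func:`read_release` at the same ordinal reproduces the snapshot
    exactly (set equality per field).  Rows are emitted in sorted order so
    output is deterministic.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def blank(schema: Sequence[str], **kw: str) -> list[str]:
        row = ["" for _ in schema]
        for k, v in kw.items():
            row[schema.index(k)] = v
        return row

    conso = [
        blank(RXNCONSO_SCHEMA, rxcui=a.rxcui, lat="ENG", ispref="Y",
              sab=RXNORM_SAB, tty=a.tty, code=a.rxcui, str=a.name)
        for a in sorted(snapshot.atoms, key=lambda a: (a.rxcui, a.tty))
    ]
    _write_rrf(directory / "RXNCONSO.RRF", RXNCONSO_SCHEMA, conso)

    sat = [
        blank(RXNSAT_SCHEMA, rxcui=n.rxcui, code=n.rxcui, atn=NDC_ATN,
              sab=RXNORM_SAB, atv=n.ndc)
        for n in sorted(snapshot.ndc_attributes, key=lambda n: (n.ndc, n.rxcui))
    ]
    _write_rrf(directory / "RXNSAT.RRF", RXNSAT_SCHEMA, sat)

    cui = [
        blank(RXNCUI_SCHEMA, cui1=r.cui1, cardinality=str(r.cardinality), cui2=r.cui2)
        for r in sorted(snapshot.retirements, key=lambda r: (r.cui1, r.cui2))
    ]
    _write_rrf(directory / "RXNCUI.RRF", RXNCUI_SCHEMA, cui)

    _write_rrf(directory / "RXNCUICHANGES.RRF", RXNCUICHANGES_SCHEMA, [])

    sab = [blank(RXNSAB_SCHEMA, vsab=f"{RXNORM_SAB}_{snapshot.version.label}",
                 rsab=RXNORM_SAB, son="RxNorm-format release",
                 sver=snapshot.version.label, curver="Y")]
    _write_rrf(directory / "RXNSAB.RRF", RXNSAB_SCHEMA, sab)

    rel = [
        blank(RXNREL_SCHEMA, rxcui1=t[0], rela=t[1], rxcui2=t[2], sab=RXNORM_SAB)
        for t in sorted(snapshot.relationships)
    ]
    _write_rrf(directory / "RXNREL.RRF", RXNREL_SCHEMA, rel)
    return directory
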