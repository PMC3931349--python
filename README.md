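# dronbuild

Build a modular OWL 2 drug ontology from a chronological series of
RxNorm-format releases.

## The problem

Pharmacy claims databases span a decade or more, so analysing them requires
a *historically complete* registry of National Drug Codes (NDCs) — yet each
release of RxNorm carries only the currently active codes, and the concept
identifiers (RXCUIs) that anchor them are retired over time: merged into
successors, withdrawn as errors, split into several concepts, or sometimes
silently dropped with no record at all.  `dronbuild` ingests every release
of such a series, tracks identifier provenance across all of these events,
accumulates every NDC ever observed, maps drug ingredients to ChEBI classes
by exact lexical matching, and emits a five-module OWL 2 ontology of drug
products, their ingredients and their molecular dispositions, in the style
of OBO Foundry drug ontologies.

Real releases are distributed under a UMLS license, so the package ships a
first-class synthetic-fixture generator that emulates the release dialect,
the identifier lifecycle events and a mini-ChEBI with known ground truth;
the whole pipeline is built and tested without licensed data.

## The model

**Provenance.**  A master conversion table maps each retired identifier to
a successor or a status code: a retirement record with `cui1 == cui2` means
*entered in error* (stored literally as `ERROR`), cardinality > 1 means
*split* (stored as `S_RXNCUI`), cardinality 1 means *merged into* `cui2`.
Identifiers that vanish with no record are kept as flagged *orphaned*
self-references.  After each ingestion the table is compacted by transitive
closure, so every entry points directly at the latest identifier naming the
same entity; error and split statuses absorb whole chains.

**NDC registry.**  Every `(NDC, RXCUI)` observation from every release is
kept with its release span; after closure each observation resolves to
`INCLUDED`, `EXCLUDED_ERROR`, `EXCLUDED_SPLIT`, or `ORPHANED`.  Excluded
codes stay in the registry for audit but appear nowhere downstream;
orphaned codes are retained (flagged) under their last known identifier so
historical claims lookups do not lose them.

**Entities.**  Six entity types are derived, keyed by terminal identifier
so merged concepts collapse into one entity: ingredients (IN), clinical
drug forms (SCDF), clinical drugs (SCD), branded drugs (SBD), packaged drug
products (one per retained NDC), and six curated molecular dispositions.
Ingredients are matched to ChEBI by exact normalized-name comparison over
`rdfs:label`, exact synonym and related synonym; unmatched ingredients get
minted IRIs under *processed material*, and a shipped override maps
somatropin to the Protein Ontology (its name lexically collides with the
ChEBI *role* 'growth hormone').  Disposition–ingredient links are mined
from ChEBI role assignments for three dispositions and manually curated
for the other three.

**Emission.**  The ontology is written as five RDF/XML modules —
`dron-upper` (curated), `dron-chebi`, `dron-pro`, `dron-rxnorm`, and the
`dron-full` connector that imports the rest.  Drug forms subclass *drug
product* and carry one existential `has_proper_part` restriction per
ingredient; clinical drugs subclass their form, branded drugs their
clinical drug; each packaged product subclasses *packaged drug product*
with exactly one `has_proper_part` restriction on its product; ingredients
carry `bearer_of` restrictions on their dispositions; every class derived
from the release series is annotated with `has_Rxcui`.  Output is
byte-deterministic for identical input.

## Worked example

Generate a five-release synthetic series with its mini-ChEBI, build the
ontology, and query the result:

```sh
$ dronbuild synth --seed 11 --out fx
wrote 5 releases, mini_chebi.owl, manifest.json under fx

$ dronbuild build --release-dir fx/release_01 --release-dir fx/release_02 \
    --release-dir fx/release_03 --release-dir fx/release_04 \
    --release-dir fx/release_05 --chebi fx/mini_chebi.owl \
    --out-db store.sqlite --out-owl owl
releases ingested: 5
entities: ingredients=12, dispositions=6, cdfs=8, cds=15, bds=8, packaged=35
ndc status: INCLUDED=49, EXCLUDED_ERROR=3, EXCLUDED_SPLIT=2, ORPHANED=0
match tally: label=6, exact_synonym=0, related_synonym=1, override=1, none=4
module classes: dron-full=0, dron-chebi=9, dron-rxnorm=70, dron-pro=2, dron-upper=13
```

The series started with 20 clinical drugs; 3 merges, 1 split and 1 error
leave 15 clinical-drug entities.  49 of the 54 distinct NDC observations
resolve to a live product; the 5 attached to the error/split victims are
excluded, leaving 35 distinct packaged products.  Of the 12 ingredients,
6 matched ChEBI labels, 1 a related synonym, 1 (somatropin) was redirected
to the Protein Ontology by the shipped override, and 4 were minted fresh
IRIs.

```sh
$ dronbuild resolve --db store.sqlite 9200000
9200000: MERGED -> 9200010

$ dronbuild ndc-status --db store.sqlite 04320171851
04320171851: rxcui=9300001 seen SYN01..SYN05 status=INCLUDED

$ dronbuild query --db store.sqlite --ingredient 9000007
31133614854
77306898575
87791378848
(3 NDCs)
```

Identifier `9200000` was merged during the series and resolves to its
terminal identifier; the query lists every NDC whose packaged product
contains ingredient `9000007`, via its drug forms, clinical drugs and
branded drugs.

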