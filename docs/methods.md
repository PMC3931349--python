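# Methods

## Scope and data flow

The package rebuilds a drug ontology from a chronological series of
RxNorm-format releases in five stages: RRF parsing and field extraction →
identifier provenance → historical NDC registry → ChEBI ingredient mapping
→ normalized entity graph → OWL 2 module emission.  Each stage is a plain
module with pure-ish functions over explicit dataclasses; the `pipeline`
module only sequences them.

## The RRF dialect

Releases are pipe-delimited, one record per line, trailing delimiter
allowed, no quoting or escaping, UTF-8.  Column layouts for the concept
(18 columns), attribute (13), retired-identifier (5), identifier-change
(6), source-metadata (25) and relationship (16) files follow the public
RxNorm documentation; the source material names the files but not their
layouts.  Only rows curated by the terminology itself (`SAB = RXNORM`) are
consumed, and only the four term types the build needs (SCDF, SCD, SBD,
IN).  The files are not referentially closed; identifiers referenced by
attributes or relationships but absent from the concept file are tolerated
and logged, never fatal.

Two deliberate extensions of the processed file set:

* **Relationships.**  The entity graph needs SCD→SCDF (`isa`), SCDF→IN
  (`has_ingredient`) and SBD→SCD (`tradename_of`) links, but the source
  never states where they come from.  An optional relationship file in the
  same dialect supplies them; without it the build still runs and the
  resulting drug classes are parented directly under *drug product*.
* **Identifier-change file.**  It is parsed (validating the dialect) and
  logged, but the provenance mapping is derived solely from the
  retired-identifier file plus disappearance detection, because no
  combination rule for the two files is documented.

## Provenance tracking

Per release, in order: (1) identifiers that reappear after being tracked
as retired are treated as current again and their entries dropped (logged;
the underlying policy is undocumented, and re-activation loses less
information than keeping a stale redirect); (2) identifiers known from
earlier releases but missing from the concept file are registered as
unresolved orphans; (3) retirement records assign successors — `cui1 ==
cui2` ⇒ `ERROR`, cardinality > 1 ⇒ `S_RXNCUI` (split), cardinality 1 ⇒
merged into `cui2`.  Records are cumulative across releases; the first
assignment for a key wins, and a key carrying both merge and split records
is a hard error listing the records.

Compaction computes the transitive closure with memoised chain-following:
every entry ends at a current identifier, an orphan, or a status code, and
`ERROR`/`S_RXNCUI` absorb the whole chain.  Cycles cannot arise from the
documented lifecycle, so one is a hard error naming the cycle rather than
a silent repair.  Compaction is idempotent, and incremental per-release
maintenance provably (by property test) agrees with a single from-scratch
chain-following pass.

`ORPHANED` is a status this artifact adds beyond the two documented codes:
identifiers that vanish with no record keep their attached data under the
last known identifier, flagged.  Dropping them silently would lose recall
for exactly the historical-claims use case the registry exists for.

## NDC registry

One entry per `(ndc, rxcui-at-observation)` pair with its release span;
nothing is ever deleted, so entry count is monotone.  After compaction each
entry resolves to one of four statuses; error- and split-attached codes are
excluded downstream (successor attribution for splits would need manual
curation), orphan-attached codes are kept and flagged.  When one code's
included entries resolve to *different* terminal identifiers (a genuinely
reused code), the observation with the latest `last_seen` wins and losers
are logged — a tie-break this artifact defines, since no rule is
documented.

## ChEBI mapping

Exact lexical matching over three annotation types: `rdfs:label`,
`oboInOwl:hasExactSynonym`, `oboInOwl:hasRelatedSynonym`.  "Exact" is
taken as byte equality after case-folding, trimming and collapsing internal
whitespace; pure byte equality would be brittle across sources.  A label
match beats synonym matches; if the winning annotation type still offers
two or more distinct classes, no mapping is made and the candidates go to
a curation report (the ingredient then receives a minted IRI).  Overrides
— shipped with one entry, somatropin → PRO somatotropin — bypass the index
entirely; somatropin's name collides with the ChEBI *role* 'growth
hormone', which names a function, not a molecule.

Snapshots load from OWL (any RDF serialization `rdflib` parses) or OBO
(via `obonet`).  Role linkage is auto-detected: existential `has role`
(RO:0000087) restrictions first, plain has-role triples as fallback, the
detected shape logged.  Role mining accepts a configured role or any of
its sub-roles, so specific role assignments still reach the broader
disposition.  Mined links can be subtracted by a curated exclusion list:
ethosuximide bears the ChEBI role *calcium channel blocker* but inhibits
T-type, not L-type, channels, so it is excluded from the L-type
disposition and curated onto the T-type one.  Curated lists and exclusions
reference ingredients by identifier or normalized name; name-based entries
make the shipped seed content applicable to any release series.

## Entity graph and relational store

Entities are keyed by *terminal* identifier, so merge events deduplicate
automatically; names are taken from the latest release, preferring the
terminal identifier's own atom.  Relationship endpoints are remapped
through resolution; edges touching an error/split endpoint are dropped and
logged.  Single-valued parents (drug form of a clinical drug, clinical
drug of a branded drug) keep the edge from the latest release when
remapping creates conflicts.  Clinical drugs with no form link are kept,
flagged dangling, and parented directly under *drug product* at emission —
dropping them would silently lose their NDCs.

The store is a single-file sqlite database with one table per entity type
(`ingredient`, `clinical_drug_form`, `clinical_drug`, `branded_drug`,
`ndc`, `disposition`) plus provenance tables (`rxcui`, `rxnorm`,
`deprecated_rxcuis`, `ndc_comp`) and explicit many-to-many tables
(`cdf_ingredient`, `disposition_ingredient`).  The validation queries —
all NDCs containing an ingredient, or an ingredient bearing a disposition
— run over the in-memory graph or a reloaded store identically; the
disposition query is by construction the union of its bearers' ingredient
queries.

## OWL emission

Five RDF/XML modules.  Class routing: curated content → `dron-upper`
(shipped statically from `data/upper_module.json`: the structural classes,
the six dispositions, `has_proper_part`, `bearer_of`, `has_Rxcui`);
ChEBI-matched ingredients and their imported superclass closure →
`dron-chebi`; PRO stubs → `dron-pro`; everything generated from the
release series → `dron-rxnorm`; `dron-full` holds only import statements.
All generated restrictions are existential (`some`) — the source names the
relations but not the quantifiers, and existentials are the weakest
commitment that supports the intended queries.  External upper-level
classes (BFO *disposition*, OBI *processed material*, RO *bearer of*, PRO
*protein*) are declared as IRI + label stubs rather than imported, keeping
the build network-free.  `has_proper_part` has no canonical RO IRI, so it
lives in the artifact's own namespace; `bearer_of` reuses RO:0000053.

Determinism: generated IRIs (`DRON_` + zero-padded 8-digit counter,
starting at 10000 to stay clear of the curated block) are assigned in
sorted order — entity type, then terminal identifier numerically, then NDC
code — so permuting the input changes nothing; restriction blank nodes get
content-derived labels; triples are serialized sorted.  Identical input
yields byte-identical files, and serialize→parse→serialize is a byte-level
fixed point after blank-node canonicalization.

No DL reasoner is bundled.  The consistency check is structural: it first
verifies the emitted axioms stay inside the fragment the emitter can
produce (atomic subsumptions and existential restrictions over named
classes, annotations — no negation, disjointness or cardinality ceilings),
in which a named class is unsatisfiable exactly when `owl:Nothing` is
among its transitive superclasses, and then walks the subsumption graph.
Anything outside that fragment raises rather than passing silently.

## Synthetic fixtures

The generator emulates the phenomena the pipeline exists to handle, not
the text statistics of real drug names.  Defaults: 12 ingredients (three
of them the worked cases furosemide / somatropin / ethosuximide), 8 drug
forms, 20 clinical drugs, 8 branded drugs, 40 NDCs, 5 releases, with 3
merges (some chained), 1 split, 1 error and 1 silent disappearance — a
small series in which every lifecycle event still occurs; the acceptance
sweep scales this to ~200 concepts per seed across 20 seeds, which runs in
about a second.  Match fractions (50 % label, 10 % exact synonym, 20 %
related synonym) keep every annotation type and the unmatched path
populated.  All randomness is drawn once into an explicit plan; release
directories and the mini-ChEBI are pure functions of the plan, hence
byte-identical per seed.

The ground-truth manifest is derived from the generator's own event
bookkeeping — which concepts it retired, where their information went,
which codes it listed where — not by running the pipeline, so manifest
comparisons are genuine oracles.  Event victims are clinical drugs;
split/error/disappearance victims are restricted to concepts without
branded children so the branded-drug parent invariant cannot be violated
by construction, and merge survivors are stable concepts or later merge
victims (chains).  Split children are existing concepts; the excluded
codes make the attribution question moot, mirroring the exclusion policy.
Decoy rows (a foreign-source ingredient, a brand-name term type, a
foreign-source NDC) are planted in every fixture to keep the extractors'
filters honest.

What passing fixture tests does *not* show about real data: name
normalization issues beyond whitespace/case, NDC format pathologies,
relationship sources that disagree across releases, split attribution, and
real-scale class counts (the historical real-series figures require
licensed releases and a specific ChEBI snapshot, and are out of scope).

## Known limitations

* Split-concept information is excluded, not attributed; recovering it
  needs manual curation.
* Dose-form linkage (*drug tablet* / *drug capsule* subclasses exist but
  are unused) and packaging structure beneath *packaged drug product* are
  not modelled.
* The mapping stage is exact-match only; no fuzzy or structure-based
  matching.
* The structural satisfiability check is sound only for the fragment the
  emitter produces; it refuses, rather than analyses, anything richer.
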