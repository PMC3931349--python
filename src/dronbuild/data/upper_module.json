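{
  "comment": "Hand-curated upper module: structural classes, the six molecular dispositions, and the properties used by the generated axioms. Stub entries stand for classes/properties whose home ontology is referenced by IRI + label only.",
  "classes": [
    {"iri": "http://purl.obolibrary.org/obo/DRON_00000005", "label": "drug product", "parent": null,
     "definition": "A material entity that contains at least one scattered molecular aggregate as proper part (its active ingredient) and that bears a clinical drug role."},
    {"iri": "http://purl.obolibrary.org/obo/DRON_00000006", "label": "drug tablet", "parent": "http://purl.obolibrary.org/obo/DRON_00000005"},
    {"iri": "http://purl.obolibrary.org/obo/DRON_00000007", "label": "drug capsule", "parent": "http://purl.obolibrary.org/obo/DRON_00000005"},
    {"iri": "http://purl.obolibrary.org/obo/DRON_00000008", "label": "packaged drug product", "parent": null,
     "definition": "A material entity consisting of a package containing some number of instances of a clinical or branded drug product."},
    {"iri": "http://purl.obolibrary.org/obo/DRON_00000009", "label": "clinical drug role", "parent": null},
    {"iri": "http://purl.obolibrary.org/obo/OBI_0000047", "label": "processed material", "parent": null, "stub": true},
    {"iri": "http://purl.obolibrary.org/obo/BFO_0000016", "label": "disposition", "parent": null, "stub": true},
    {"iri": "http://purl.obolibrary.org/obo/DRON_00000011", "label": "non-activating competitive beta-adrenergic receptor binding disposition", "parent": "http://purl.obolibrary.org/obo/BFO_0000016"},
    {"iri": "http://purl.obolibrary.org/obo/DRON_00000012", "label": "function-inhibiting hydrogen/potassium adenosine triphosphatase enzyme (H+/K+ ATPase) binding disposition", "parent": "http://purl.obolibrary.org/obo/BFO_0000016"},
    {"iri": "http://purl.obolibrary.org/obo/DRON_00000013", "label": "function-inhibiting L-type voltage-gated calcium channel binding disposition", "parent": "http://purl.obolibrary.org/obo/BFO_0000016"},
    {"iri": "http://purl.obolibrary.org/obo/DRON_00000014", "label": "function-inhibiting vitamin K epoxide reductase binding disposition", "parent": "http://purl.obolibrary.org/obo/BFO_0000016"},
    {"iri": "http://purl.obolibrary.org/obo/DRON_00000015", "label": "function-inhibiting Na-K-Cl cotransporter 2 (NKCC2) binding disposition", "parent": "http://purl.obolibrary.org/obo/BFO_0000016"},
    {"iri": "http://purl.obolibrary.org/obo/DRON_00000016", "label": "function-inhibiting T-type calcium channel binding disposition", "parent": "http://purl.obolibrary.org/obo/BFO_0000016"}
  ],
  "object_properties": [
    {"iri": "http://purl.obolibrary.org/obo/DRON_00000090", "label": "has_proper_part"},
    {"iri": "http://purl.obolibrary.org/obo/RO_0000053", "label": "bearer_of", "stub": true}
  ],
  "annotation_properties": [
    {"iri": "http://purl.obolibrary.org/obo/DRON_00000099", "label": "has_Rxcui"}
  ]
}
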