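# disposition label	ChEBI role IRI (blank = manually curated ingredient list)
non-activating competitive beta-adrenergic receptor binding disposition	http://purl.obolibrary.org/obo/CHEBI_35530
function-inhibiting hydrogen/potassium adenosine triphosphatase enzyme (H+/K+ ATPase) binding disposition	http://purl.obolibrary.org/obo/CHEBI_49200
function-inhibiting L-type voltage-gated calcium channel binding disposition	http://purl.obolibrary.org/obo/CHEBI_38808
function-inhibiting vitamin K epoxide reductase binding disposition	
function-inhibiting Na-K-Cl cotransporter 2 (NKCC2) binding disposition	
function-inhibiting T-type calcium channel binding disposition	
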