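# ingredient name	target IRI
somatropin	http://purl.obolibrary.org/obo/PR_000007204
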