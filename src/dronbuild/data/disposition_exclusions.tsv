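# disposition label	ingredient (identifier or name) to remove from mined links
function-inhibiting L-type voltage-gated calcium channel binding disposition	ethosuximide
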