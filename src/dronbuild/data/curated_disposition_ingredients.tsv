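# disposition label	ingredient (identifier or name)
function-inhibiting vitamin K epoxide reductase binding disposition	warfarin
function-inhibiting Na-K-Cl cotransporter 2 (NKCC2) binding disposition	furosemide
function-inhibiting T-type calcium channel binding disposition	ethosuximide
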