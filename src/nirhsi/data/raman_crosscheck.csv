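category,count
PE,250
PP,31
non_polymer,16
not_evaluable,53
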