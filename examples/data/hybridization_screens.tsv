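probe_set	positives	clones_screened
chloroplast/Pv_ABa	209	36864
chloroplast/Pv_ABb	62	36864
mitochondria/Pv_ABa	79	36864
mitochondria/Pv_ABb	23	36864
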