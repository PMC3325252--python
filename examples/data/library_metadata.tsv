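library_id	clone_count	mean_insert	empty_fraction	organellar_fraction
Pv_ABa	101376	144000	0.01	0.0078
Pv_ABb	101376	110000	0.01	0.0023
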