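domain_name	aa_start	aa_end	critical
Walker-B_beta4	237	247	true
beta5	268	278	true
beta6	305	315	true
beta7	320	330	true
beta8	335	345	true
beta9	350	360	true
NLS	366	370	true
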