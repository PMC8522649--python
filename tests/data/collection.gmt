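synaptic_signaling	demo term	G00000	G00001	G00002	G00003	G00004
axonogenesis	demo term	G00002	G00005	G00006
cognition	demo term	G00007	G00008	G00009	G00010
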