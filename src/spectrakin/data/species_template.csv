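# Blank transcription template: one row per tracked species.
# units: one of "nm2 ns-1", "1e-9 m2 s-1", "m2 s-1".
name, diffusion_coefficient, units
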