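# Blank transcription template: radiation-chemical yields, species per 100 eV.
species, g_value
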