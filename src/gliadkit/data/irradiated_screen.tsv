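population	lines_changed	lines_tested
Paragon_gamma_irradiated_M4	14	360
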