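# Range of net redistributed charge on the analyte (e).
bound	value_e
lower	-0.100
upper	0.035
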