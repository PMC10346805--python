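# Mean binding energy (eV) over the analyte panel, per peptide.
peptide	mean_ebind_ev
CRQVF	-0.8
CIHNP	-0.69
DSWAADIP	-0.59
WHVSC	-0.55
DNPIQAVP	-0.51
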