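# Most-active center and its acetone binding energy (eV) per peptide.
peptide	center	ebind_ev
CIHNP	e	-0.71
CRQVF	a	-0.90
DNPIQAVP	a	-0.68
DSWAADIP	d	-0.61
WHVSC	g	-0.56
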