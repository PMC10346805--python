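# Extreme minimum peptide-analyte distances (angstrom).
peptide	analyte	min_distance_A
DSWAADIP	ethanol	1.700
WHVSC	methanol	2.562
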