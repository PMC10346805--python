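# Mean binding energy (eV) over the peptides, for the analytes with
# published averages; molar masses g/mol.
analyte	mean_ebind_ev	molar_mass_g_mol
trinitrotoluene	-1.216	227.13
ammonia	-0.59	18.039
hexane	-0.47	86.178
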