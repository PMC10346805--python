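# SYNTHETIC stand-in absolute energies (eV) whose difference equals the
# published CIHNP/acetone center-e binding energy.
quantity	energy_ev
e_complex	-1050.71
e_host	-1000.00
e_analyte	-50.00
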