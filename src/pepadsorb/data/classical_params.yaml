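# Default parameters of the classical surrogate energy model.
# sigma: 12-6 Lennard-Jones size per element, angstrom (UFF-derived).
# epsilon: LJ well depth per element, eV (UFF-derived).
# Combination rules: sigma arithmetic mean, epsilon geometric mean.
sigma:
  H: 2.5711
  C: 3.4309
  N: 3.2607
  O: 3.1181
  S: 3.5948
epsilon:
  H: 0.0019080
  C: 0.0045532
  N: 0.0029921
  O: 0.0026018
  S: 0.0118818
coulomb_constant: 14.3996   # eV * angstrom / e^2
spring_constant: 2.0        # eV / angstrom^2, intramolecular elastic network
network_cutoff: 3.0         # angstrom, springs between reference pairs closer than this
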