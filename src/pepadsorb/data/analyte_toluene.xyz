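15
toluene idealized geometry with reference partial charges (e)
C 2.202476 -0.251313 -0.141285 -0.039776
C 0.717114 -0.081891 -0.021137 -0.051133
C 0.149311 1.197834 0.010018 -0.059326
C -1.235449 1.355211 0.090105 -0.062005
C -2.064293 0.235554 0.129152 -0.062249
C -1.509385 -1.042006 0.083830 -0.062005
C -0.124772 -1.200674 0.003739 -0.059326
H 2.730599 0.574357 0.347154 0.027965
H 2.491461 -0.281575 -1.196313 0.027965
H 2.530429 -1.177354 0.342572 0.027965
H 0.783253 2.080730 -0.027130 0.062550
H -1.667270 2.352042 0.119109 0.062278
H -3.142170 0.358565 0.190591 0.062269
H -2.154974 -1.915857 0.107938 0.062278
H 0.293669 -2.203621 -0.038345 0.062550
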