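12
benzene idealized geometry with reference partial charges (e)
C -1.376989 0.220664 0.027374 -0.062269
C -0.879819 -1.082333 0.003699 -0.062269
C 0.497169 -1.302997 -0.023675 -0.062269
C 1.376988 -0.220664 -0.027374 -0.062269
C 0.879819 1.082333 -0.003699 -0.062269
C -0.497169 1.302997 0.023675 -0.062269
H -2.449822 0.392581 0.048701 0.062269
H -1.565304 -1.925591 0.006581 0.062269
H 0.884528 -2.318180 -0.042120 0.062269
H 2.449820 -0.392592 -0.048702 0.062269
H 1.565295 1.925598 -0.006580 0.062269
H -0.884516 2.318184 0.042120 0.062269
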