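4
ammonia idealized geometry with reference partial charges (e)
N -0.007259 -0.006869 0.295427 -0.343926
H 0.928405 -0.156497 -0.079416 0.114642
H -0.597624 -0.720190 -0.130016 0.114642
H -0.323522 0.883556 -0.085996 0.114642
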