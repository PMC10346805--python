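20
hexane idealized geometry with reference partial charges (e)
C 2.975466 0.484576 -0.195221 -0.065382
C 1.476812 0.670043 -0.011541 -0.056172
C 0.796702 -0.642794 0.378644 -0.053579
C -0.695522 -0.487535 0.685455 -0.053579
C -1.528671 -0.090692 -0.533854 -0.056172
C -3.013461 -0.060126 -0.204365 -0.065382
H 3.186472 -0.245857 -0.982815 0.023035
H 3.444673 0.137375 0.730864 0.023035
H 3.442847 1.433230 -0.477311 0.023035
H 1.055178 1.054825 -0.946125 0.026371
H 1.300715 1.425842 0.762475 0.026371
H 0.933123 -1.382662 -0.419516 0.026643
H 1.288272 -1.048602 1.271690 0.026643
H -0.831879 0.251603 1.484302 0.026643
H -1.065124 -1.444298 1.075134 0.026643
H -1.356622 -0.801188 -1.350516 0.026371
H -1.230126 0.899577 -0.893737 0.026371
H -3.223729 0.661981 0.591064 0.023035
H -3.591643 0.229050 -1.087567 0.023035
H -3.363484 -1.044348 0.122940 0.023035
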