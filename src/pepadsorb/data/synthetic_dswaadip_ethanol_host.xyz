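20
SYNTHETIC peptide-fragment stand-in; complex realizes a 1.700 A minimum distance
C 0.000000 0.000000 0.000000 0.581580
C -0.288585 -1.772708 -1.994169 -0.015184
N -2.206174 -0.494313 0.040934 0.017629
O -4.178877 0.133999 -0.304146 -0.450000
H 3.754510 1.163036 0.127059 -0.009864
H -0.028139 -2.272366 -4.393854 -0.055703
H -2.768381 1.728289 -2.694539 -0.000576
C -3.109850 -2.091606 3.422989 -0.022179
O 0.088117 3.124352 1.257455 0.058306
H 2.175939 -3.676540 0.370294 0.032654
C 0.069950 3.342054 -1.248623 -0.001207
N 0.883657 -3.966735 -1.011314 0.033419
H -1.592673 -3.148202 2.847043 -0.016993
H -1.084984 4.308731 0.809925 0.052606
O 0.945506 1.241969 1.588052 -0.000270
C -3.142908 -0.537179 -2.343924 0.029169
H -0.877515 -3.629663 4.210452 -0.064545
H 3.366693 1.459933 -3.315458 0.017334
C 3.105669 4.004534 3.635251 -0.084410
H 0.627472 -3.190860 -2.767829 -0.101766
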