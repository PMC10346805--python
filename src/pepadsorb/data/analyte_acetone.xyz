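10
acetone idealized geometry with reference partial charges (e)
C -1.190240 -0.357158 -0.354064 -0.005962
C 0.051511 -0.370766 0.495754 0.126268
C 1.162364 0.557804 0.085777 -0.005962
O 0.153505 -1.104923 1.477418 -0.300344
H -1.631524 0.642460 -0.341791 0.031000
H -0.937015 -0.645479 -1.377228 0.031000
H -1.917698 -1.069778 0.044393 0.031000
H 1.500236 0.302389 -0.921559 0.031000
H 0.805754 1.590353 0.113864 0.031000
H 2.003107 0.455098 0.777437 0.031000
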