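6
methanol idealized geometry with reference partial charges (e)
C -0.370308 -0.023670 -0.010757 0.031939
O 0.958352 -0.470214 -0.209667 -0.399630
H -0.537873 0.161961 1.053002 0.052687
H -0.537080 0.892709 -0.582211 0.052687
H -1.060543 -0.796729 -0.356558 0.052687
H 1.547453 0.235943 0.106191 0.209630
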