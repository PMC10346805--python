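9
ethanol idealized geometry with reference partial charges (e)
C -0.869315 0.037157 -0.246258 -0.041838
C 0.469267 -0.408544 0.304716 0.040221
O 1.294139 0.721477 0.548734 -0.396664
H -1.523053 -0.821231 -0.424215 0.025373
H -1.364549 0.720934 0.450953 0.025373
H -0.738672 0.581535 -1.187293 0.025373
H 0.335457 -0.943567 1.249380 0.056070
H 0.981764 -1.072260 -0.398218 0.056070
H 1.414961 1.184499 -0.297798 0.210022
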