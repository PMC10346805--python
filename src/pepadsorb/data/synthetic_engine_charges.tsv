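# SYNTHETIC engine-style analyte charges before/after adsorption (e);
# net transfer per entry lies in the published range.
analyte	atom_index	q_before_e	q_after_e
acetone	0	-0.005962	-0.004065
acetone	1	0.126268	0.116396
acetone	2	-0.005962	-0.016607
acetone	3	-0.300344	-0.319069
acetone	4	0.031000	0.029238
acetone	5	0.031000	0.017125
acetone	6	0.031000	0.043980
acetone	7	0.031000	0.037958
acetone	8	0.031000	0.025894
acetone	9	0.031000	0.027150
ethanol	0	-0.041838	-0.057925
ethanol	1	0.040221	0.033615
ethanol	2	-0.396664	-0.419464
ethanol	3	0.025373	0.010731
ethanol	4	0.025373	0.012856
ethanol	5	0.025373	0.018060
ethanol	6	0.056070	0.069539
ethanol	7	0.056070	0.048081
ethanol	8	0.210022	0.199507
ammonia	0	-0.343926	-0.341823
ammonia	1	0.114642	0.123991
ammonia	2	0.114642	0.114546
ammonia	3	0.114642	0.123286
trinitrotoluene	0	-0.026009	-0.040070
trinitrotoluene	1	0.104720	0.102516
trinitrotoluene	2	0.285564	0.285860
trinitrotoluene	3	0.063043	0.063688
trinitrotoluene	4	-0.258294	-0.255394
trinitrotoluene	5	-0.258294	-0.280278
trinitrotoluene	6	0.094500	0.089707
trinitrotoluene	7	0.282704	0.296079
trinitrotoluene	8	0.062748	0.065613
trinitrotoluene	9	-0.258302	-0.261151
trinitrotoluene	10	-0.258302	-0.259183
trinitrotoluene	11	0.094500	0.090133
trinitrotoluene	12	0.285564	0.262539
trinitrotoluene	13	0.063043	0.059892
trinitrotoluene	14	-0.258294	-0.276597
trinitrotoluene	15	-0.258294	-0.257946
trinitrotoluene	16	0.028481	0.032791
trinitrotoluene	17	0.028481	0.012302
trinitrotoluene	18	0.028481	0.013104
trinitrotoluene	19	0.076980	0.091481
trinitrotoluene	20	0.076980	0.066914
benzene	0	-0.062269	-0.058526
benzene	1	-0.062269	-0.068809
benzene	2	-0.062269	-0.056075
benzene	3	-0.062269	-0.071499
benzene	4	-0.062269	-0.071700
benzene	5	-0.062269	-0.049323
benzene	6	0.062269	0.081454
benzene	7	0.062269	0.062259
benzene	8	0.062269	0.064323
benzene	9	0.062269	0.073148
benzene	10	0.062269	0.055886
benzene	11	0.062269	0.069862
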