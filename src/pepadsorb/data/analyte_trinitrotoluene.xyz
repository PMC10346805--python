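21
trinitrotoluene idealized geometry with reference partial charges (e)
C -2.420570 -0.090974 0.517994 -0.026009
C -0.946679 -0.036047 0.205913 0.104720
C -0.210646 -1.192995 -0.126314 0.285564
N -0.865531 -2.492175 -0.226175 0.063043
O -0.410678 -3.400400 0.478880 -0.258294
O -1.809692 -2.587232 -1.018636 -0.258294
C 1.170238 -1.163523 -0.385810 0.094500
C 1.843694 0.061260 -0.337568 0.282704
N 3.286441 0.110580 -0.611514 0.062748
O 3.854816 -0.956940 -0.873019 -0.258302
O 3.838626 1.216986 -0.566909 -0.258302
C 1.152356 1.241752 -0.046956 0.094500
C -0.228278 1.178261 0.207745 0.285564
N -0.902236 2.444787 0.469324 0.063043
O -0.459101 3.129520 1.398649 -0.258294
O -1.849423 2.741209 -0.267861 -0.258294
H -3.004807 0.033885 -0.398704 0.028481
H -2.709526 0.683848 1.235291 0.028481
H -2.696753 -1.037976 0.992619 0.028481
H 1.699814 -2.086239 -0.625568 0.076980
H 1.667935 2.202411 -0.021383 0.076980
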