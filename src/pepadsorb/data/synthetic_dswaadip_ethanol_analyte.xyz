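9
SYNTHETIC ethanol placement; closest pair is analyte-H ... host-H at 1.700 A
C 6.108248 2.021424 0.305016 -0.041838
C 7.446830 1.575723 0.855990 0.040221
O 8.271702 2.705744 1.100008 -0.396664
H 5.454510 1.163036 0.127059 0.025373
H 5.613014 2.705201 1.002227 0.025373
H 6.238891 2.565802 -0.636019 0.025373
H 7.313020 1.040700 1.800654 0.056070
H 7.959327 0.912007 0.153056 0.056070
H 8.392524 3.168766 0.253476 0.210022
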