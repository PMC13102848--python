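name	x	y
A1	-1.133333	0.000000
A2	1.133333	0.000000
AF3	-0.269920	0.743026
AF4	0.269920	0.743026
AF7	-0.587785	0.809017
AF8	0.587785	0.809017
AFz	0.000000	0.600000
C1	-0.250000	0.000000
C2	0.250000	0.000000
C3	-0.500000	0.000000
C4	0.500000	0.000000
C5	-0.750000	0.000000
C6	0.750000	0.000000
CP1	-0.230580	-0.260736
CP2	0.230580	-0.260736
CP3	-0.466022	-0.302840
CP4	0.466022	-0.302840
CP5	-0.706216	-0.321982
CP6	0.706216	-0.321982
CPz	0.000000	-0.200000
Cz	0.000000	0.000000
F1	-0.184531	0.488070
F2	0.184531	0.488070
F3	-0.380781	0.553307
F4	0.380781	0.553307
F5	-0.588912	0.589915
F6	0.588912	0.589915
F7	-0.809017	0.587785
F8	0.809017	0.587785
FC1	-0.230580	0.260736
FC2	0.230580	0.260736
FC3	-0.466022	0.302840
FC4	0.466022	0.302840
FC5	-0.706216	0.321982
FC6	0.706216	0.321982
FCz	0.000000	0.200000
FT10	1.141268	0.370820
FT7	-0.951057	0.309017
FT8	0.951057	0.309017
FT9	-1.141268	0.370820
Fp1	-0.309017	0.951057
Fp2	0.309017	0.951057
Fpz	0.000000	0.800000
Fz	0.000000	0.400000
Iz	0.000000	-1.200000
M1	-1.152303	-0.182507
M2	1.152303	-0.182507
O1	-0.309017	-0.951057
O2	0.309017	-0.951057
Oz	0.000000	-0.800000
P1	-0.184531	-0.488070
P10	0.970820	-0.705342
P2	0.184531	-0.488070
P3	-0.380781	-0.553307
P4	0.380781	-0.553307
P5	-0.588912	-0.589915
P6	0.588912	-0.589915
P7	-0.809017	-0.587785
P8	0.809017	-0.587785
P9	-0.970820	-0.705342
PO3	-0.269920	-0.743026
PO4	0.269920	-0.743026
PO7	-0.587785	-0.809017
PO8	0.587785	-0.809017
POz	0.000000	-0.600000
Pz	0.000000	-0.400000
T7	-1.000000	0.000000
T8	1.000000	0.000000
TP10	1.141268	-0.370820
TP7	-0.951057	-0.309017
TP8	0.951057	-0.309017
TP9	-1.141268	-0.370820
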