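# 120-channel International 10-5 montage on a head sphere
# columns: label x y z (cm); x right, y nasion, z up
# head_radius_cm 8.817118
Fpz	0.00000	8.81700	-0.04633
AFz	0.00000	8.24995	3.11125
Fz	0.00000	6.53808	5.91567
FCz	0.00000	3.85127	7.93154
FCCz	0.00000	2.26725	8.52063
Cz	0.00000	0.61256	8.79581
CPz	0.00000	-2.60340	8.42401
Pz	0.00000	-5.39888	6.97091
POz	0.00000	-7.55274	4.54947
Oz	0.00000	-8.70590	1.39603
Fp1	-2.48848	8.44431	-0.49263
Fp2	2.48848	8.44431	-0.49263
AF7	-4.77342	7.36765	-0.82085
AF3	-2.99112	8.05910	1.96104
AF4	2.99112	8.05910	1.96104
AF8	4.77342	7.36765	-0.82085
F7	-6.73243	5.60666	-0.99066
F5	-6.17079	6.07492	1.66083
F3	-4.66236	6.38849	3.89758
F1	-2.51987	6.49711	5.40179
F2	2.51987	6.49711	5.40179
F4	4.66236	6.38849	3.89758
F6	6.17079	6.07492	1.66083
F8	6.73243	5.60666	-0.99066
FT7	-8.18391	3.12055	-1.01359
FC5	-7.69722	3.48803	2.51555
FC3	-5.84721	3.76659	5.41890
FC1	-3.11754	3.84525	7.29634
FC2	3.11754	3.84525	7.29634
FC4	5.84721	3.76659	5.41890
FC6	7.69722	3.48803	2.51555
FT8	8.18391	3.12055	-1.01359
T7	-8.77516	0.07381	-0.85598
C5	-8.26256	0.29847	3.06311
C3	-6.27795	0.47049	6.17313
C1	-3.33103	0.57989	8.14307
C2	3.33103	0.57989	8.14307
C4	6.27795	0.47049	6.17313
C6	8.26256	0.29847	3.06311
T8	8.77516	0.07381	-0.85598
TP7	-8.31213	-2.88363	-0.57854
CP5	-7.75324	-2.86523	3.06908
CP3	-5.84769	-2.74899	5.99909
CP1	-3.13218	-2.62392	7.81320
CP2	3.13218	-2.62392	7.81320
CP4	5.84769	-2.74899	5.99909
CP6	7.75324	-2.86523	3.06908
TP8	8.31213	-2.88363	-0.57854
P7	-6.93808	-5.43949	-0.12873
P5	-6.27540	-5.55943	2.73014
P3	-4.75573	-5.46557	5.02516
P1	-2.54279	-5.40048	6.48927
P2	2.54279	-5.40048	6.48927
P4	4.75573	-5.46557	5.02516
P6	6.27540	-5.55943	2.73014
P8	6.93808	-5.43949	-0.12873
PO7	-4.95012	-7.28795	0.35164
PO3	-3.24011	-7.48241	3.35512
PO4	3.24011	-7.48241	3.35512
PO8	4.95012	-7.28795	0.35164
O1	-2.58550	-8.38437	0.87127
O2	2.58550	-8.38437	0.87127
FCC3h	-4.82313	2.22277	7.03835
FCC4h	4.82313	2.22277	7.03835
FFC5h	-6.29762	5.07567	3.50985
FFC6h	6.29762	5.07567	3.50985
C1h	-1.67745	0.60652	8.63481
C2h	1.67745	0.60652	8.63481
CCP1h	-1.66845	-1.03858	8.59530
CCP2h	1.66845	-1.03858	8.59530
FCC1h	-1.65835	2.27692	8.35507
FCC2h	1.65835	2.27692	8.35507
CP1h	-1.59063	-2.59825	8.27409
CP2h	1.59063	-2.59825	8.27409
FC1h	-1.58306	3.84043	7.77731
FC2h	1.58306	3.84043	7.77731
CPP1h	-1.45541	-4.07930	7.68001
CPP2h	1.45541	-4.07930	7.68001
C3h	-4.88155	0.53542	7.32294
C4h	4.88155	0.53542	7.32294
FFC1h	-1.44770	5.26950	6.91940
FFC2h	1.44770	5.26950	6.91940
CCP3h	-4.83035	-1.11031	7.29222
CCP4h	4.83035	-1.11031	7.29222
CP3h	-4.56235	-2.67587	7.05452
CP4h	4.56235	-2.67587	7.05452
FC3h	-4.56018	3.82397	6.50565
FC4h	4.56018	3.82397	6.50565
P1h	-1.29947	-5.38551	6.85924
P2h	1.29947	-5.38551	6.85924
CPP3h	-4.17247	-4.13586	6.57470
CPP4h	4.17247	-4.13586	6.57470
F1h	-1.28263	6.53361	5.77999
F2h	1.28263	6.53361	5.77999
FFC3h	-4.14432	5.27297	5.72380
FFC4h	4.14432	5.27297	5.72380
P3h	-3.70642	-5.44325	5.86302
P4h	3.70642	-5.44325	5.86302
PPO2h	1.11458	-6.55995	5.78502
PPO1h	-1.11458	-6.55995	5.78502
F3h	-3.66351	6.44874	4.76803
F4h	3.66351	6.44874	4.76803
AFF2h	1.07409	7.51949	4.47718
AFF1h	-1.07409	7.51949	4.47718
C5h	-7.42156	0.39081	4.74440
C6h	7.42156	0.39081	4.74440
CCP5h	-7.31627	-1.23636	4.76290
CCP6h	7.31627	-1.23636	4.76290
FCC5h	-7.31527	2.02992	4.48418
FCC6h	7.31527	2.02992	4.48418
PPO4h	3.19670	-6.54383	4.97001
PPO3h	-3.19670	-6.54383	4.97001
CP5h	-6.93876	-2.81128	4.65745
CP6h	6.93876	-2.81128	4.65745
FC5h	-6.93243	3.61342	4.07751
FC6h	6.93243	3.61342	4.07751
AFF3h	-3.06773	7.39754	3.68876
AFF4h	3.06773	7.39754	3.68876
CPP5h	-6.34289	-4.24402	4.41561
CPP6h	6.34289	-4.24402	4.41561
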