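trait	s_ldsc_pve	si_ldsc_pve	si_p
Basophil	0.0363	0.0375	0.4728
BMI	0.2100	0.2482	0.8126
Cholesterol	0.1042	0.1358	0.6202
CRP	0.0452	0.0524	0.6483
DBP	0.1228	0.1441	0.6125
EGFR	0.1826	0.2105	0.8507
Eosinophil	0.1403	0.1578	0.1867
HBA1C	0.1040	0.1275	0.6917
HDL	0.1820	0.2373	0.5754
Height	0.4315	0.4726	0.5224
Hematocrit	0.1416	0.1646	0.3956
Hemoglobin	0.1504	0.1795	0.2299
LDL	0.0858	0.1131	0.8812
Lymphocyte	0.0545	0.0651	0.1453
MCH	0.1497	0.1545	0.0968
MCHC	0.0450	0.0496	0.3728
MCV	0.1814	0.1930	0.1530
Monocyte	0.1085	0.1431	0.5421
Neutrophil	0.1320	0.1599	0.2499
Platelet	0.2317	0.2628	0.7371
RBC	0.1933	0.2223	0.3197
SBP	0.1206	0.1419	0.1100
Triglycerides	0.1335	0.1621	0.5301
Urate	0.1530	0.1736	0.1177
WBC	0.1221	0.1482	0.5155
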