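trait	ukb_ldsc	ukb_ildsc	ukb_theta	ukb_p	bbj_ldsc	bbj_ildsc	bbj_theta	bbj_p
Basophil	0.0250	0.0315	0.0065	1.572e-12	0.0684	0.1548	0.0864	0.025
BMI	0.1757	0.2349	0.0592	3.083e-84	0.1667	0.2656	0.0989	2.438e-18
Cholesterol	0.0954	0.0974	0.0020	1.821e-16	0.0629	0.1268	0.0639	2.740e-4
CRP	0.0354	0.0414	0.0060	9.845e-12	0.0202	0.1625	0.1423	0.020
DBP	0.0940	0.1203	0.0263	1.118e-65	0.0605	0.1267	0.0662	1.675e-7
EGFR	0.1521	0.1999	0.0478	1.187e-46	0.1010	0.1225	0.0215	4.232e-5
Eosinophil	0.1055	0.1375	0.0320	1.230e-18	0.0785	0.1973	0.1188	0.001
HBA1C	0.0906	0.1083	0.0177	1.578e-26	0.1057	0.1308	0.0251	0.031
HDL	0.1599	0.1768	0.0169	9.636e-37	0.1590	0.1838	0.0248	0.081
Height	0.3675	0.4815	0.1140	1.038e-64	0.3941	0.7336	0.3395	7.433e-33
Hematocrit	0.1078	0.1352	0.0274	2.479e-25	0.0752	0.0928	0.0176	3.689e-5
Hemoglobin	0.1177	0.1433	0.0256	4.284e-27	0.0702	0.0752	0.0050	9.037e-4
LDL	0.0802	0.0859	0.0057	5.087e-13	0.0745	0.1438	0.0693	0.018
Lymphocyte	0.0402	0.0501	0.0099	4.906e-19	0.0844	0.1757	0.0913	5.479e-5
MCH	0.1361	0.1597	0.0236	1.785e-25	0.1536	0.2831	0.1295	1.042e-5
MCHC	0.0317	0.0364	0.0047	3.730e-12	0.0571	0.0650	0.0079	0.027
MCV	0.1630	0.1902	0.0272	1.180e-29	0.1530	0.2818	0.1288	1.042e-5
Monocyte	0.0788	0.0955	0.0167	5.257e-18	0.0888	0.1549	0.0661	0.004
Neutrophil	0.1102	0.1391	0.0289	1.777e-33	0.1191	0.2114	0.0923	5.050e-5
Platelet	0.1992	0.2447	0.0455	2.303e-37	0.1565	0.2436	0.0871	7.724e-9
RBC	0.1574	0.1933	0.0359	3.292e-31	0.1203	0.2068	0.0865	5.972e-8
SBP	0.0954	0.1201	0.0247	8.660e-75	0.0769	0.1604	0.0835	9.075e-10
Triglycerides	0.1061	0.1204	0.0143	1.410e-26	0.1171	0.2670	0.1499	0.110
Urate	0.1217	0.1550	0.0333	9.642e-38	0.1395	0.3462	0.2067	0.015
WBC	0.0962	0.1250	0.0288	9.866e-34	0.1024	0.2266	0.1242	1.346e-8
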