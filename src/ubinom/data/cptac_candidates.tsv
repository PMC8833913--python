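protein_id	clinical_log2fc	clinical_adj_p
FTL	2.53	4.2e-12
SLC16A3	2.32	1.9e-52
PLOD2	2.29	7.4e-33
PYGL	2.04	2.1e-43
SCARB1	1.95	9.8e-34
TGM2	1.62	1.4e-37
GYS1	1.52	1.7e-44
HLA-B	1.26	1.1e-30
NEK6	1.24	1.3e-51
DPP9	1.12	6e-53
APOL2	1.11	2.8e-24
ERGIC1	1.09	1.1e-35
UBE2L6	1.07	1e-61
OAS3	1.02	5.3e-44
ALDOA	1.01	7.6e-57
PLEKHA2	0.98	4.1e-49
MYO9B	0.97	9.6e-69
IMPDH1	0.95	8.3e-49
TGFBI	0.93	2.4e-15
TRIM22	0.92	8.9e-49
EHD2	0.88	8e-28
HLA-C	0.87	1.7e-19
RUNX1	0.87	2.7e-37
ANXA2	0.86	7.7e-49
PARP14	0.85	3.8e-48
FNDC3B	0.81	3.8e-46
ASNS	0.78	1.7e-27
AMPD2	0.76	1.3e-38
LAMB2	0.75	1.1e-26
HMOX1	0.74	1.2e-29
RHBDF2	0.74	1.6e-38
PARP9	0.74	3.3e-38
SMC4	0.72	2.7e-45
DDX60	0.71	4e-40
HM13	0.7	1.4e-23
DENND3	0.7	2.1e-47
RNF213	0.7	5.1e-35
NFKB2	0.67	1.1e-39
APAF1	0.67	9.5e-53
RRP1	0.64	3.1e-53
SRM	0.64	6.9e-33
CAD	0.63	5.5e-56
SLC39A14	0.61	2e-10
HELZ2	0.61	1.4e-27
TBC1D2	0.61	7.8e-29
CNDP2	0.6	3.9e-23
CDK17	0.59	7.3e-45
GFPT1	0.59	1.9e-29
ARHGEF1	0.59	4.5e-55
NAP1L1	0.57	3.7e-45
IPO9	0.56	4.1e-64
MTHFD2	0.54	4.8e-16
ASCC3	0.54	3.9e-57
COL6A2	0.52	5.1e-16
TBC1D2B	0.51	2.5e-36
PPIP5K2	0.51	1.1e-41
GSDMD	0.51	1.3e-41
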