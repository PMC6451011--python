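TRAIT	SNP	CHR	BP	EA	OA	FREQ	BETA	SE	P	GENE
L5 timing	rs1144566	1	82569626	C	T	0.970	0.096	0.014	8E-12	RGS16/RNASEL
L5 timing	rs113851554	2	66750564	T	G	0.057	0.133	0.011	2E-35	MEIS1
L5 timing	rs12991815	2	68071990	C	G	0.424	0.029	0.005	2E-09	C1D
L5 timing	rs9369062	6	38437303	A	C	0.708	0.039	0.005	9E-14	BTBD9
L5 timing	rs4882315	12	38458906	T	C	0.507	0.027	0.005	2E-08	CPNE8/ALG10B
L5 timing	rs12927162	16	52684916	G	A	0.277	0.029	0.005	3E-08	TOX3
M10 timing	rs1973293	12	38679575	C	T	0.481	0.029	0.005	1E-09	CPNE8/ALG10B
Sleep duration	rs2660302	1	98520219	A	T	0.811	0.041	0.006	9E-12	DPYD
Sleep duration	rs113851554	2	66750564	G	T	0.943	0.110	0.011	2E-25	MEIS1
Sleep duration	rs62158170	2	114082175	G	A	0.217	0.054	0.006	3E-21	PAX8
Sleep duration	rs17400325	2	178565913	T	C	0.958	0.066	0.012	2E-08	PDE11A
Sleep duration	rs72828540	6	19102286	T	C	0.752	0.041	0.005	1E-13	LOC101928519
Sleep duration	rs9369062	6	38437303	C	A	0.292	0.033	0.005	2E-10	BTBD9
Sleep duration	rs2975734	8	10090097	C	G	0.561	0.027	0.005	1E-08	MSRA
Sleep duration	rs13282541	8	41723550	C	T	0.739	0.032	0.005	4E-09	ANK1
Sleep duration	rs2880370	8	105987057	A	T	0.670	0.028	0.005	2E-08	LRP12/ZFPM2
Sleep duration	rs800165	12	67645219	C	T	0.343	0.028	0.005	3E-08	CAND1
Sleep duration	rs10138240	14	63353479	G	C	0.514	0.029	0.005	7E-10	KCNH5
Sleep midpoint	rs11892220	2	231691067	T	A	0.339	0.029	0.005	3E-08	CAB39
Sleep efficiency	rs113851554	2	66750564	G	T	0.943	0.101	0.011	5E-22	MEIS1
Sleep efficiency	rs62158169	2	114081827	T	C	0.216	0.032	0.006	2E-08	PAX8
Sleep efficiency	rs17400325	2	178565913	T	C	0.958	0.074	0.012	2E-10	PDE11A
Sleep efficiency	rs13094687	3	52450043	G	A	0.315	0.029	0.005	1E-08	PHF7
Sleep efficiency	rs13080973	3	138596050	G	A	0.202	0.032	0.006	3E-08	FOXL2
No. sleep episodes	rs12714404	2	282462	T	G	0.283	0.037	0.005	1E-12	ACP1/SH3YL1
No. sleep episodes	rs310727	3	4336589	T	C	0.475	0.026	0.005	3E-08	SUMF1/SETMAR
No. sleep episodes	rs55754932	3	87847754	C	A	0.284	0.037	0.005	2E-12	HTR1F
No. sleep episodes	rs9864672	3	137076353	T	C	0.522	0.029	0.005	2E-10	IL20RB/SOX14
No. sleep episodes	rs4974697	4	2473092	T	A	0.390	0.026	0.005	5E-08	RNF4
No. sleep episodes	rs7377083	4	102708997	A	C	0.430	0.029	0.005	2E-09	BANK1
No. sleep episodes	rs749100	5	63307862	A	G	0.582	0.033	0.005	9E-12	HTR1A/RNF180
No. sleep episodes	rs9341399	6	73773644	C	T	0.936	0.066	0.010	6E-12	KCNQ5
No. sleep episodes	rs1889978	6	124771233	C	T	0.485	0.027	0.005	5E-09	NKAIN2
No. sleep episodes	rs2141277	7	39099178	A	G	0.478	0.026	0.005	1E-08	POU6F2
No. sleep episodes	rs10233848	7	103122645	G	A	0.293	0.035	0.005	2E-11	RELN
No. sleep episodes	rs1124116	10	99371147	A	G	0.730	0.031	0.005	2E-09	HOGA1/MORN4
No. sleep episodes	rs4755731	11	43685168	G	A	0.431	0.028	0.005	3E-09	HSD17B12
No. sleep episodes	rs3751837	16	3583173	C	T	0.781	0.033	0.006	4E-09	CLUAP1
No. sleep episodes	rs8045740	16	20262776	G	T	0.868	0.052	0.007	6E-14	GPR139
No. sleep episodes	rs11078917	17	37746359	A	C	0.279	0.029	0.005	3E-08	NEUROD2
No. sleep episodes	rs11082030	18	35501739	T	C	0.725	0.030	0.005	8E-09	CELF4
No. sleep episodes	rs8098424	18	52458218	G	A	0.619	0.027	0.005	1E-08	RAB27B
No. sleep episodes	rs76753486	19	42684264	T	C	0.084	0.047	0.008	2E-08	DEDD2/ZNF526
No. sleep episodes	rs429358	19	45411941	T	C	0.848	0.036	0.007	4E-08	APOE
No. sleep episodes	rs12479469	20	61145196	A	G	0.342	0.031	0.005	4E-10	MIR133A2
Diurnal inactivity	rs17805200	9	13764434	C	T	0.272	0.031	0.005	5E-09	MPDZ/NFIB
Diurnal inactivity	rs7155227	14	63365094	T	G	0.523	0.033	0.005	2E-12	KCNH5
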