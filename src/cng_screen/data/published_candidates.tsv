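gene	transcript	chrom	start1	end1	unit	region	ref_units	control_min	control_max	unstable
ANKUB1	NM_001315506	chr3	149484688	149484745	CTG	3'UTR	20	14	33	1
BACH2	NM_001170794.1	chr6	90718564	90718564	CTG	5'UTR	10	6	8	0
BCL6B	NM_181844	chr17	6928020	6928047	CAG	CDS	10	15	17	0
BMPR2	NM_001204	chr2	203241237	203241267	CGG	5'UTR	11	15	19	0
CAPN6	NM_014289	chrX	110513720	110513753	CAG	5'UTR	12	11	15	0
CASK	NM_003688	chrX	41376788	41376833	CTG	3'UTR	16	18	23	0
CBL	NM_005188	chr11	119077000	119077034	CGG	5'UTR	12	14	19	0
CIZ1	NM_001131015.1	chr9	130950197	130950197	CTG	5'UTR	10	7	8	0
CNKSR2	NM_014927	chrX	21392714	21392747	CAG	5'UTR	12	7	17	1
E2F4	NM_001950	chr16	67229794	67229830	CAG	CDS	13	14	19	0
EIF4G3	NM_001198801	chr1	21502761	21502791	CGG	5'UTR	11	12	18	0
EP400	NM_015409	chr12	132547094	132547133	CAG	CDS	14	10	21	1
ERF	NM_001308402	chr19	42758006	42758035	CGG	5'UTR	10	11	20	1
FAM193B	NM_001190946	chr5	176981515	176981551	CGG	5'UTR	13	11	17	0
FOXP2	NM_148900	chr7	114055052	114055052	CAG	5'UTR	10	5	6	0
GIPC1	NM_005716	chr19	14606924	14606951	CGG	5'UTR	10	8	22	1
GLS	NM_014905	chr2	191745600	191745642	CAG	5'UTR	15	6	29	1
GSPT1	NM_002094	chr16	12009243	12009270	CGG	CDS	10	15	18	0
HDAC2	NM_001527.4	chr6	114292073	114292073	CTG	5'UTR	10	8	9	0
HTR7P1	NR_002774.3	chr12	13153376	13153376	CAG	5'UTR	10	8	17	1
IRF2BPL	NM_024496	chr14	77492087	77492114	CAG	CDS	10	8	13	0
JPH3	NM_001271604	chr16	87637890	87637933	CTG	CDS	15	13	24	1
KANSL1L	NM_001307976	chr2	211035902	211035953	CGG	5'UTR	17	14	18	0
LARP6	NM_197958	chr15	71146430	71146461	CGG	5'UTR	11	12	15	0
MAB21L1	NM_005584	chr13	36050618	36050672	CAG	5'UTR	19	7	26	1
MAGI1	NM_001033057	chr3	65425651	65425678	CAG	CDS	10	13	18	0
MAML3	NM_018717	chr4	140812077	140812116	CAG	CDS	14	18	26	1
MAP3K4	NM_001291958	chr6	161519351	161519381	CTG	CDS	11	13	16	0
MED15	NM_001293234	chr22	20920814	20920847	CAG	CDS	12	14	21	1
MEF2A	NM_001130927	chr15	100252710	100252740	CAG	CDS	11	13	25	1
MIR205HG	NM_001104548	chr1	209605639	209605669	CAG	CDS	11	6	17	1
MLLT3	NM_001286691	chr9	20413769	20413796	CAG	CDS	10	12	24	1
MPRIP	NM_201274	chr17	17039562	17039592	CAG	CDS	11	13	16	0
NCOR2	NM_001206654	chr12	124886962	124886995	CAG	CDS	12	14	23	1
NPPB	NM_002521.2	chr1	11918891	11918891	CTG	5'UTR	10	6	8	0
PCDH19	NM_001184880	chrX	99664130	99664157	CGG	5'UTR	10	12	18	0
PDCD1	NM_005018	chr2	242792336	242792367	CTG	3'UTR	11	12	13	0
PDS5A	NM_001100399	chr4	39979441	39979471	CGG	5'UTR	10	13	17	0
PIM1	NM_002648	chr6	37137922	37137922	CAG	5'UTR	10	8	9	0
POU6F2	NM_007252	chr7	39379288	39379315	CAG	CDS	10	13	16	0
RAI1	NM_030665	chr17	17697094	17697130	CAG	CDS	13	11	17	1
RAPH1	NM_213589	chr2	204399869	204399905	CAG	5'UTR	10	6	10	0
RBM39	NM_001323423.1	chr20	34328797	34328797	CTG	5'UTR	10	5	7	0
RPL14	NM_001034996	chr3	40503521	40503548	CTG	CDS	10	13	21	1
S100A16	NM_001317007	chr1	153579768	153579795	CAG	3'UTR	10	15	16	0
TMEM132A	NM_178031	chr11	60691967	60691998	CGG	5'UTR	10	14	17	0
TREML2	NM_024807	chr6	41159019	41159056	CAG	3'UTR	10	11	12	0
UBE2B	NM_003337	chr5	133707165	133707192	CGG	5'UTR	10	14	17	0
UMAD1	NM_001302350	chr7	7712940	7712998	CAG	5'UTR	20	15	28	1
USF3	NM_001009899	chr3	113377918	113377948	CAG	CDS	11	13	20	1
VEZF1	NM_007146	chr17	56056545	56056578	CAG	CDS	12	19	21	0
ZNF384	NM_133476	chr12	6777048	6777087	CAG	CDS	14	16	22	0
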