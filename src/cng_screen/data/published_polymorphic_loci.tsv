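gene	cohort	ref_units	n_chromosomes	n_alleles	min_units	max_units	mean	sd	median	hi	thousand_genomes_range	brain_expression
ANKUB1	control	20	52	14	14	33	21.38	5.94	21	0.85	6-26	Present
ANKUB1	case	20	178	18	8	31	22.49	5.87	24	0.91	6-26	Present
CNKSR2	control	12	166	11	7	17	11.42	1.28	11	0.2	-	Present
CNKSR2	case	12	190	8	6	15	11.57	1.23	11	0.09	-	Present
EP400	control	14	56	7	11	20	17.71	1.71	17.5	0.54	11-28	Present
EP400	case	14	188	11	10	21	18.16	1.44	19	0.5	11-28	Present
ERF	control	10	128	9	11	20	14.45	2.11	15.5	0.23	6-11	Present
ERF	case	10	120	8	12	21	15.32	1.71	16	0.25	6-11	Present
GIPC1	control	10	168	11	8	22	13.97	1.61	14	0.27	6-22	Present
GIPC1	case	10	148	8	8	18	13.90	1.30	14	0.3	6-22	Present
GLS	control	15	166	13	6	29	11.28	3.31	12	0.78	5-24	Present
GLS	case	15	188	12	6	21	11.61	3.40	12	0.89	5-24	Present
HTR7P1	control	10	166	6	8	17	13.93	3.93	17	0.61	-	Present
HTR7P1	case	10	188	9	7	17	9.81	1.30	10	0.52	-	Present
JPH3	control	15	132	6	13	24	21.30	1.69	20	0.61	5-19	Present
JPH3	case	15	178	7	19	25	21.02	1.20	20	0.56	5-19	Present
MAB21L1	control	19	166	18	8	26	16.27	4.07	16.5	0.94	5-26	Present
MAB21L1	case	19	152	18	8	26	17.70	4.35	19	0.91	5-26	Present
MAML3	control	14	58	7	18	26	21.38	1.36	21	0.44	4-20	Present
MAML3	case	14	188	9	17	28	21.65	1.60	21	0.34	4-20	Present
MED15	control	12	52	5	14	21	15.50	1.09	15	0.27	9-13	Present
MED15	case	12	186	7	8	19	15.16	0.87	15	0.33	9-13	Present
MEF2A	control	11	52	6	13	25	14.67	2.32	14	0.69	2-14	Present
MEF2A	case	11	170	10	8	22	14.27	1.70	14	0.61	2-14	Present
MIR205HG	control	11	54	10	6	17	11.67	2.37	11	0.44	3-17	Not Present
MIR205HG	case	11	184	7	6	17	12.19	2.15	11	0.46	3-17	Not Present
MLLT3	control	10	180	7	12	24	16.97	0.77	17	0.07	-	Present
MLLT3	case	10	190	5	14	22	16.97	0.59	17	0.05	-	Present
NCOR2	control	12	158	9	11	23	18.86	1.79	19	0.46	4-15	Present
NCOR2	case	12	176	7	15	23	19.88	1.04	20	0.51	4-15	Present
RAI1	control	13	90	7	10	17	14.87	2.09	16	0.34	6-14	Present
RAI1	case	13	184	9	10	18	15.86	1.03	16	0.46	6-14	Present
RPL14	control	10	52	8	13	21	18.25	1.78	18	0.69	-	Present
RPL14	case	10	190	10	12	21	17.99	1.65	18	0.79	-	Present
UMAD1	control	20	52	9	15	28	23.31	2.84	23	0.62	4-24	Present
UMAD1	case	20	190	16	14	31	23.41	2.39	23	0.78	4-24	Present
USF3	control	11	166	5	15	20	16.71	0.89	17	0.52	6-16	Present
USF3	case	11	184	7	9	20	16.78	1.30	17	0.62	6-16	Present
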