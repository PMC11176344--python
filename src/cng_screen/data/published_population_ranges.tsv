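gene	AFR	AMR	EAS	EUR	SAS	control	case
MIR205HG	13 (4-18)	9 (4-18)	9 (3-14)	9 (3-14)	9 (4-16)	11 (6-17)	11 (6-17)
GLS	14 (5-24)	8 (5-23)	8 (6-21)	8 (6-22)	14 (6-26)	12 (6-29)	12 (6-21)
USF3	13 (6-15)	13 (7-17)	13 (8-16)	13 (6-16)	13 (6-17)	17 (15-20)	17 (9-20)
ANKUB1	11 (8-25)	11 (9-27)	11 (6-26)	11 (7-26)	11 (6-26)	15 (14-33)	15 (8-31)
MAML3	18 (4-20)	18 (8-19)	18 (4-18)	18 (6-19)	18 (8-18)	21 (18-26)	21 (17-28)
UMAD1	18 (7-25)	17 (6-25)	17 (4-24)	17 (6-24)	17 (6-25)	23 (15-28)	23 (14-31)
NCOR2	17 (10-21)	18 (13-22)	18 (10-21)	18 (4-22)	18 (11-22)	19 (11-23)	20 (15-23)
EP400	28 (12-29)	28 (12-29)	28 (12-29)	28 (11-29)	28 (12-29)	17 (11-20)	19 (10-21)
MAB21L1	11 (5-27)	13 (6-26)	17 (4-26)	13 (6-27)	13 (5-26)	13 (8-26)	13 (8-26)
MEF2A	11 (2-16)	11 (2-13)	9 (2-16)	11 (3-13)	9 (2-14)	14 (13-25)	15 (8-22)
JPH3	15 (6-26)	15 (9-19)	15 (10-19)	15 (10-20)	15 (7-25)	20 (13-24)	20 (19-25)
RAI1	12 (6-15)	12 (7-15)	12 (5-13)	12 (6-14)	12 (6-14)	16 (10-17)	16 (10-18)
GIPC1	13 (6-22)	14 (9-17)	14 (6-18)	14 (12-20)	14 (7-22)	14 (8-29)	14 (8-18)
ERF	9 (6-10)	9 (8-10)	9 (9-9)	9 (8-11)	9 (6-11)	16 (11-20)	16 (12-21)
MED15	12 (12-12)	12 (12-12)	12 (12-12)	12 (9-13)	12 (11-12)	15 (14-21)	15 (8-19)
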