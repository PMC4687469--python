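case_id	region_or_karyotype	size_mb	disorder	exome	driver_mutations	mean_baf	methylation	size_footnote
E7173	chr14: 70924501-105930406	35.0	ET	Yes	SF3B1 K700E	0.81	0.45	
E5364	chr14: 94245652-105417313	11.2	CMML	Yes	EZH2 exon9:c.729-2A>-	0.91	0.49	
E6459	chr14: 33291583-105930406	72.6	PMF	Yes	JAK2 V617F; TET2 D1242V	0.73	0.52	
PT03B08	chr14:20211644-107285437	87.1	PMF	—	CALR Type 2	0.82	0.28	
CB44	chr14:22053729-107285437	85.2	ET	—	CALR Type 1	0.74	0.05	
PT02B05	chr14:73672831-107274052	33.6	ET	—	MPL W515K	0.8	0.25	
PT02E11	chr14:23582569-107220898	83.6	ET	—	CALR Type 2	0.8	0.27	
AN804	chr14:21240673-107285437	86.0	PMF	—	CALR Type 1	0.80	0.32	
11_4629	chr14:21209871-107287663	86.1	ET	—	CALR Type 2	0.71	0.21	
E6430	chr14:23102969-107274052	84.2	ET	—	CALR Type 1	0.64	0.12	
E09853	chr14:20213937-107274052	87.1	PV	—	JAK2 V617F	0.62	−0.10	
E09861	chr14:20295510-107274052	87.0	PV	—	JAK2 V617F	0.77	0.19	
E09895	chr14:56103882-107287663	51.1	PV	—	JAK2 V617F	0.71	0.22	
E09984	chr14:50192257-107287663	57.1	ET	—	JAK2 V617F	0.79	0.31	
H3589_11	chr14:59183573-107287663	48.1	PV	—	JAK2 V617F	0.58	0.07	
H10872_10	chr14:24653187-107222493	82.6	PV	—	JAK2 V617F	0.58	0.12	
W1212280	chr14:24843620-107287663	82.4	PV	—	JAK2 V617F	0.57	0.07	
H131_12	chr14:92280675-107274052	15.0	PV	—	JAK2 V617F	0.63	0.07	
PT1544	chr14: 94238353- 107287663	13.0	ET	—	CALR Type 2	0.69	ND	
PT1645	chr14: 21070264- 105965102	84.9	ET	—	JAK2 V617F	0.89	ND	
PT1670	chr14: 23248583- 107287663	84.0	ET	—	JAK2 V617F	0.79	ND	
PT1876	chr14: 72220169- 107231967	35.0	ET	—	JAK2 V617F	0.89	ND	
G_735	chr14:27349540-107349540	80	PMF	—	JAK2 V617F	NA	0.40	b
G_3358	chr14:83349540-107349540	24	PMF	—	JAK2 V617F	NA	0.52	b
G_3499	chr14:101250540-107349540	6	PMF	—	JAK2 V617F	NA	0.19	b
ULSAM 546	chr14:24944467-107349540	82.4	PC	Yes	None detected	0.69	0.07	
ULSAM 831	chr14:40334000-107349540	67.0	PC	Yes	None detected	0.67	ND	
PIVUS 931	chr14:94156220-107331190	13.2	PC	Yes	JAK2 V617F; TP53 exon6:c.376-2 A>G	0.77	ND	
PIVUS 892	chr14:77435975-107349540	29.9	PC	Yes	None detected	0.61	ND	
E4051	+14	—	aCML	Yes			0.15	
E6901	+14	—	CMML	—			−0.14	
W813483	46,XX,?dup(12)(p11p12),idic(14) (p11)/47,idem,+idic(14)	—	AML	—			0.29	
W1301891	47,XX,+14[20]	—	MDS	—			0.12	
W1407109	46,XX,del(5)(q13q33)[1]/58,sl,+1,+2,+del(5),+8,+9,+10,+11,+13,+14,+19,+21,+22[9]/60,sdl1,+6,add(6)(q1),+mar[2]	—	MDS	—			0.11	
W1409489	45,X,-Y[6]/46,idem,+14[8]/46,XY[6]	—	MDS	—			−0.13	
E7820	aUPD14q by microsatellite analysis	—	CMML	—	EZH2 C590F			
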