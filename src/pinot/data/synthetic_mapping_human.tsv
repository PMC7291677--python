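symbol	uniprot	entrez
ATP13A2	Q9NQ11	23400
FBXO7	Q9Y3I1	25793
GBA	P04062	2629
PINK1	Q9BXM7	65018
SMPD1	P17405	6609
VPS35	Q96QK1	55737
SNCA	P37840	6622
PRKN	O60260	5071
LRRK2	Q5S007	120892
CYCS	P99999	54205
TP53	P04637	7157
EGFR	P00533	1956
AKT1	P31749	207
MAPT	P10636	4137
HSPA8	P11142	3312
UBC	P0CG48	7316
UBE2L3	P68036	7332
SQSTM1	Q13501	8878
OPTN	Q96CV9	10133
TOMM20	Q15388	9804
TOMM70	O94826	9868
MFN1	Q8IWA4	55669
MFN2	O95140	9927
RHOT1	Q8IXI2	55288
RHOT2	Q8IXI1	89941
VDAC1	P21796	7416
CTSD	P07339	1509
PSAP	P07602	5660
SCARB2	Q14108	950
RAB7A	P51149	7879
WASHC2C	Q9Y4E1	253725
FAM21A	Q641Q2	387680
SNX1	Q13596	6642
SNX2	O60749	6643
TBK1	Q9UHD2	29110
ULK1	O75385	8408
GABARAPL1	Q9H0R8	23710
MAP1LC3B	Q9GZQ8	81631
PARK7	Q99497	11315
HTRA2	O43464	27429
PLA2G6	O60733	8398
DNAJC6	O75061	9829
SYNJ1	O43426	8867
VPS13C	Q709C8	54832
GRN	P28799	2896
CHCHD2	Q9Y6H1	51142
GCH1	P30793	2643
STX1A	Q16623	6804
BST1	Q10588	683
DUPA	Q9ZZZ9	900001
DUPB	Q9ZZZ9	900002
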