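CD274	individual immune marker (PD-L1)	CD274
PDCD1	individual immune marker (PD-1)	PDCD1
PDCD1LG2	individual immune marker (PD-L2)	PDCD1LG2
CTLA4	individual immune marker	CTLA4
IL2RA	individual immune marker	IL2RA
IL2RB	individual immune marker	IL2RB
IL2RG	individual immune marker	IL2RG
CXCL9	individual immune marker	CXCL9
CXCL10	individual immune marker	CXCL10
IFI27	individual immune marker	IFI27
IFIT1	individual immune marker	IFIT1
IFIT2	individual immune marker	IFIT2
IFIT3	individual immune marker	IFIT3
MX1	individual immune marker	MX1
MX2	individual immune marker	MX2
OAS2	individual immune marker	OAS2
STAT1	individual immune marker	STAT1
STAT2	individual immune marker	STAT2
STAT3	individual immune marker	STAT3
STAT4	individual immune marker	STAT4
STAT5A	individual immune marker (STAT5)	STAT5A
TBX21	individual immune marker	TBX21
ITGA1	individual immune marker (CD49A)	ITGA1
ITGAE	individual immune marker (CD103)	ITGAE
CD28	individual immune marker	CD28
TNFRSF9	individual immune marker (4-1BB)	TNFRSF9
CD40	individual immune marker	CD40
NFAT5	individual immune marker (NFAT)	NFAT5
Type_I_IFN	type I interferon gene module	IFNA14	IFNA13	IFNA6	IFNA7	IFNA5	IFNA4	IFNA1	IFNA2	IFNA16	IFNAB1	IFNK	IL6
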