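NEURONAL	provisional starter list (synthetic placeholder scale); replace with a curated neuronal program for real data	DCX	L1CAM	SYP	CHGA	NCAM1	STMN2	TUBB3	ELAVL3
IFN	provisional starter list; replace with a curated interferon-response program for real data	ISG15	IFIT1	IFIT2	IFIT3	IFI6	MX1	OAS1	STAT1
APOPTOTIC	provisional starter list; replace with a curated cell-death program for real data	BNIP3	BNIP3L	DDIT3	GADD45A	PMAIP1	BBC3
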