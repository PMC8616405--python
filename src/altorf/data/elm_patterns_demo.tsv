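elm_id	elm_class	regex
LIG_WW_1	WW domain ligand	PP.Y
LIG_WW_4	WW domain ligand	[ST]P
LIG_SH3_1	SH3 domain ligand	[RKY]..P..P
LIG_SH3_3	SH3 domain ligand	P..P.[KR]
LIG_USP7_1	USP7 binding	[PA][^P][^FYWIL]S[^P]
LIG_CtBP	CtBP ligand	P.DLS
MOD_SUMO_1	Sumoylation site	[VILMAFP]K.E
MOD_CK2_1	CK2 phosphosite	[ST]..[DE]
MOD_GSK3_1	GSK3 phosphosite	[ST]...[ST]
MOD_PKA_2	PKA phosphosite	[RK][RK].[ST]
DOC_CKS1_1	Cks1 ligand	[MPVLIFWYQ].[TS]P..
DEG_SCF_TRCP1_1	SCF-TrCP phosphodegron	D[ST]G..[ST]
LIG_PDZ_3	PDZ ligand	[DE].[IVL]$
TRG_ENDOCYTIC_2	Endocytic sorting	Y..[LMVIF]
LIG_14-3-3_2	14-3-3 ligand	R..[ST].P
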