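pair_id,ligand_genes,receptor_genes,direction
MIF_CD74-CD44,MIF,CD74+CD44,ligand_to_receptor
MIF_CXCR4,MIF,CXCR4,ligand_to_receptor
IL18_IL18R,IL18,IL18R1+IL18RAP,ligand_to_receptor
CD48_CD244,CD48,CD244,ligand_to_receptor
FAM3C_KIR2DL3,FAM3C,KIR2DL3,ligand_to_receptor
CD47_SIRPA,CD47,SIRPA,ligand_to_receptor
CCL3_CCR1,CCL3,CCR1,ligand_to_receptor
CCL3_CCR5,CCL3,CCR5,ligand_to_receptor
CCL5_CCR5,CCL5,CCR5,ligand_to_receptor
AREG_EGFR,AREG,EGFR,ligand_to_receptor
GRN_SORT1,GRN,SORT1,ligand_to_receptor
TNFRSF14_CD160,TNFRSF14,CD160,ligand_to_receptor
CLEC2B_KLRF1,CLEC2B,KLRF1,ligand_to_receptor
CXCL12_CXCR4,CXCL12,CXCR4,ligand_to_receptor
TNFSF13B_TNFRSF13B,TNFSF13B,TNFRSF13B,ligand_to_receptor
TNFSF13B_TNFRSF17,TNFSF13B,TNFRSF17,ligand_to_receptor
TNFSF13_TNFRSF13B,TNFSF13,TNFRSF13B,ligand_to_receptor
IL6_IL6R,IL6,IL6R+IL6ST,ligand_to_receptor
IL7_IL7R,IL7,IL7R,ligand_to_receptor
IL15_IL15RA,IL15,IL15RA,ligand_to_receptor
IL10_IL10R,IL10,IL10RA+IL10RB,ligand_to_receptor
TGFB1_TGFBR,TGFB1,TGFBR1+TGFBR2,ligand_to_receptor
VEGFA_FLT1,VEGFA,FLT1,ligand_to_receptor
VEGFA_KDR,VEGFA,KDR,ligand_to_receptor
ICAM1_LFA1,ICAM1,ITGAL+ITGB2,ligand_to_receptor
LGALS9_HAVCR2,LGALS9,HAVCR2,ligand_to_receptor
CD274_PDCD1,CD274,PDCD1,ligand_to_receptor
CD80_CTLA4,CD80,CTLA4,ligand_to_receptor
CD86_CD28,CD86,CD28,ligand_to_receptor
SELPLG_SELL,SELPLG,SELL,ligand_to_receptor
CD40LG_CD40,CD40LG,CD40,ligand_to_receptor
CXCL8_CXCR1,CXCL8,CXCR1,ligand_to_receptor
CXCL8_CXCR2,CXCL8,CXCR2,ligand_to_receptor
TNF_TNFRSF1A,TNF,TNFRSF1A,ligand_to_receptor
TNF_TNFRSF1B,TNF,TNFRSF1B,ligand_to_receptor
IFNG_IFNGR,IFNG,IFNGR1+IFNGR2,ligand_to_receptor
IL1B_IL1R,IL1B,IL1R1+IL1RAP,ligand_to_receptor
HGF_MET,HGF,MET,ligand_to_receptor
KITLG_KIT,KITLG,KIT,ligand_to_receptor
FLT3LG_FLT3,FLT3LG,FLT3,ligand_to_receptor
CSF1_CSF1R,CSF1,CSF1R,ligand_to_receptor
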