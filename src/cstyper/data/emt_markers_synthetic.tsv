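# Synthetic stand-in EMT marker panel: 81 canonical epithelial/mesenchymal
# marker genes with polarity labels. Editable; replace with any curated
# two-column (gene, polarity) list to change the scoring panel.
gene	polarity
CDH1	epithelial
EPCAM	epithelial
CLDN1	epithelial
CLDN3	epithelial
CLDN4	epithelial
CLDN7	epithelial
OCLN	epithelial
DSP	epithelial
KRT7	epithelial
KRT8	epithelial
KRT18	epithelial
KRT19	epithelial
ESRP1	epithelial
ESRP2	epithelial
GRHL2	epithelial
RAB25	epithelial
CDS1	epithelial
MARVELD2	epithelial
MARVELD3	epithelial
TJP3	epithelial
F11R	epithelial
CRB3	epithelial
LLGL2	epithelial
PRSS8	epithelial
SPINT1	epithelial
SPINT2	epithelial
MAP7	epithelial
EPN3	epithelial
ST14	epithelial
IRF6	epithelial
VIM	mesenchymal
FN1	mesenchymal
CDH2	mesenchymal
ZEB1	mesenchymal
ZEB2	mesenchymal
SNAI1	mesenchymal
SNAI2	mesenchymal
TWIST1	mesenchymal
TWIST2	mesenchymal
FOXC2	mesenchymal
PRRX1	mesenchymal
MMP2	mesenchymal
MMP3	mesenchymal
MMP9	mesenchymal
MMP14	mesenchymal
SPARC	mesenchymal
COL1A1	mesenchymal
COL1A2	mesenchymal
COL3A1	mesenchymal
COL5A1	mesenchymal
COL5A2	mesenchymal
COL6A1	mesenchymal
COL6A2	mesenchymal
COL6A3	mesenchymal
FBN1	mesenchymal
THBS1	mesenchymal
THBS2	mesenchymal
POSTN	mesenchymal
TNC	mesenchymal
TGFB1	mesenchymal
TGFB1I1	mesenchymal
TGFBI	mesenchymal
VCAN	mesenchymal
LUM	mesenchymal
DCN	mesenchymal
BGN	mesenchymal
FAP	mesenchymal
PDGFRA	mesenchymal
PDGFRB	mesenchymal
ACTA2	mesenchymal
TAGLN	mesenchymal
CALD1	mesenchymal
MYL9	mesenchymal
FSTL1	mesenchymal
AXL	mesenchymal
S100A4	mesenchymal
CDH11	mesenchymal
WNT5A	mesenchymal
SERPINE1	mesenchymal
TIMP1	mesenchymal
EMP3	mesenchymal
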