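gene_id	class
SERINC2	TMG
PTPRF	TMG
S100A16	TMG
EFNA1	TMG
SOX4	TMG
PERP	TMG
HSPB1	TMG
ASPH	TMG
LAPTM4B	TMG
BNIP3	TMG
EPS8L2	TMG
CCND1	TMG
CTTN	TMG
KRT18	TMG
CKAP4	TMG
CKB	TMG
SEMA4B	TMG
TNFRSF12A	TMG
CRNDE	TMG
GCSH	TMG
DMKN	TMG
SDC4	TMG
CDC42EP1	TMG
HOOK2	TMG
TMEM54	TMG
UGDH	TMG
TFG	TMG
FLNB	TMG
ENO1	TMG
P4HB	TMG
S100A10	TMG
TRIP6	TMG
SCD	TMG
TMEM9	TMG
SPR	TMG
TM4SF1	TMG
MIF	TMG
ARPC1A	TMG
HIST1H1C	TMG
HDGF	TMG
POLD2	TMG
AHCY	TMG
PAFAH1B3	TMG
POP7	TMG
NHP2	TMG
PDIA4	TMG
CKS1B	TMG
ALDOA	TMG
LTBR	TMG
TMEM141	TMG
PSMB5	TMG
WDR34	TMG
HSBP1L1	TMG
AP1S1	TMG
PDCD5	TMG
NDUFB4	TMG
H1F0	TMG
HSBP1	TMG
TPI1	TMG
CTNND1	TMG
SEC61G	TMG
SPINT1	TMG
AGPAT2	TMG
LGALS3BP	TMG
POLR2I	TMG
UQCRQ	TMG
TIMM13	TMG
NDUFC1	TMG
COX6C	TMG
SNRPE	TMG
NDUFB9	TMG
PRDX5	TMG
ANXA2	TMG
TNFRSF1B	NMG
CD52	NMG
LAPTM5	NMG
CD53	NMG
CD2	NMG
CTSS	NMG
S100A4	NMG
RCSD1	NMG
RGS1	NMG
PTPRC	NMG
ZFP36L2	NMG
CXCR4	NMG
ARHGAP15	NMG
CYTIP	NMG
WIPF1	NMG
HCLS1	NMG
GZMA	NMG
HLA-A	NMG
HLA-E	NMG
HLA-C	NMG
HLA-B	NMG
GPSM3	NMG
HLA-DQA1	NMG
HLA-DPB1	NMG
IKZF1	NMG
GIMAP4	NMG
SLA	NMG
SRGN	NMG
LSP1	NMG
CTSW	NMG
UCP2	NMG
CD69	NMG
ARHGDIB	NMG
BIN2	NMG
GLIPR1	NMG
ALOX5AP	NMG
LCP1	NMG
EVL	NMG
B2M	NMG
CORO1A	NMG
CYBA	NMG
ACAP1	NMG
EVI2B	NMG
EVI2A	NMG
CCL5	NMG
CCL4	NMG
FMNL1	NMG
DDX5	NMG
CD7	NMG
MYO1F	NMG
FXYD5	NMG
HCST	NMG
GMFG	NMG
CD37	NMG
NKG7	NMG
CST7	NMG
STK4	NMG
SAMSN1	NMG
ITGB2	NMG
PIK3IP1	NMG
TMSB4X	NMG
IL2RG	NMG
CALM1	NMG
ABI3	NMG
GIMAP7	NMG
CD3D	NMG
TRAF3IP3	NMG
RHOG	NMG
CD247	NMG
IL10RA	NMG
LCK	NMG
PSMB9	NMG
FNBP1	NMG
CD3E	NMG
STK17B	NMG
FGL2	NMG
PPP1R18	NMG
RGS2	NMG
CD4	NMG
ARL6IP5	NMG
GPR65	NMG
FERMT3	NMG
LCP2	NMG
GPR183	NMG
BTG1	NMG
RHOH	NMG
ANKRD44	NMG
DUSP2	NMG
PTPN7	NMG
SEPT6	NMG
LYZ	NMG
TBC1D10C	NMG
DOK2	NMG
PARVG	NMG
AKNA	NMG
GLIPR2	NMG
FYN	NMG
SMAP2	NMG
CREM	NMG
CD96	NMG
PRDM1	NMG
ENTPD1	NMG
GZMK	NMG
ITM2A	NMG
CD3G	NMG
HIF1A	NMG
EEF1A1	NMG
LTB	NMG
DOCK8	NMG
CLEC2D	NMG
PSME1	NMG
FOXP1	NMG
SELPLG	NMG
RUNX3	NMG
RILPL2	NMG
PTPN22	NMG
PTPN6	NMG
SYTL3	NMG
STAT4	NMG
PTGER4	NMG
IL16	NMG
RASSF5	NMG
CD27	NMG
FLI1	NMG
CD8A	NMG
TAGAP	NMG
APBB1IP	NMG
NCF4	NMG
PPP2R5C	NMG
STX11	NMG
DEF6	NMG
ARHGAP9	NMG
RASAL3	NMG
SASH3	NMG
INPP5D	NMG
EPSTI1	NMG
LIPA	NMG
RGCC	NMG
PSMB10	NMG
RGS19	NMG
CTSC	NMG
ARID5A	NMG
ETS1	NMG
LPXN	NMG
SPOCK2	NMG
TCF4	NMG
STK17A	NMG
CCND2	NMG
SERPINB9	NMG
AKAP13	NMG
SH2D1A	NMG
CD74	NMG
ARHGEF1	NMG
IL7R	NMG
TNFAIP3	NMG
MFNG	NMG
ZNF331	NMG
SH2D2A	NMG
CARD8	NMG
ISG20	NMG
CSK	NMG
CNOT6L	NMG
USP15	NMG
ARHGAP4	NMG
PIM1	NMG
PPM1K	NMG
DAZAP2	NMG
SRSF5	NMG
ZFP36	NMG
AAK1	NMG
TERF2IP	NMG
JUNB	NMG
PLK3	NMG
FGFR1OP2	NMG
NFKBIA	NMG
ICAM3	NMG
ARL4C	NMG
SKAP1	NMG
IRF1	NMG
ANXA6	NMG
G3BP2	NMG
TNFAIP8	NMG
GALM	NMG
CFD	NMG
SEPT1	NMG
CCDC85B	NMG
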