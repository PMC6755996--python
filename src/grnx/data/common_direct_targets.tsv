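gene	conserved_site
ABCC5	0
ACER2	0
AEN	1
ALDH4A1	0
APAF1	1
ATP6V1H	0
BAX	1
BBC3	1
BLOC1S2	1
BMP7	1
BTG2	1
CCNG1	1
CDKN1A	1
CHST14	1
CPEB2	1
CSNK1G1	1
DDR1	0
DGKA	1
DYRK3	1
EDA2R	1
EI24	1
ELL	1
EPHA2	1
EPHX1	0
FAM212B	1
FAS	0
FBXW7	1
FDXR	1
FITM2	1
FRMD8	0
GDF15	0
GRHL3	0
GSS	1
HAGH	0
HEXIM1	0
HRAS	1
IKBIP	1
ITPKC	1
KCTD11	0
KLHDC7A	1
LIF	1
LTBP2	0
MDM2	1
MFGE8	0
MRI1	0
MRPL39	1
NINJ1	0
NOTCH1	1
NTN4	1
PARD6G	1
PERP	0
PHLDA3	1
PIDD1	1
PLAU	0
PLK2	1
PLTP	1
PLXNB2	1
PMAIP1	1
PML	0
PPM1D	1
PRKD2	0
RAP2B	1
RASL11A	0
RHOD	0
RIN1	1
RIN2	0
RPS27L	1
SAC3D1	1
SESN2	1
SLC12A4	1
SLC4A11	0
SPRYD4	0
SULF2	1
SUSD6	1
SYTL1	1
TMBIM1	0
TMEM63B	1
TP53	1
TP53INP1	1
TRAF4	1
TRIAP1	1
TRIM32	1
TSKU	1
ZMAT3	1
ZNF219	1
ZNF385A	0
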