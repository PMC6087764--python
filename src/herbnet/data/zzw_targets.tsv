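gene	protein_name	uniprot
ABCB1	Multidrug resistance protein 1	P08183
ABCB4	Multidrug resistance protein 3	P21439
ABCC1	Multidrug resistance-associated protein 1	P33527
ABCC2	Canalicular multispecific organic anion transporter 1	Q92887
ABCC3	Canalicular multispecific organic anion transporter 2	O15438
ABCG2	ATP-binding cassette sub-family G member 2	Q9UNQ0
ABL1	Tyrosine-protein kinase ABL1	P00519
ACE	Angiotensin-converting enzyme	P12821
ACP1	Low molecular weight phosphotyrosine protein phosphatase	P24666
ADIPOQ	Adiponectin	Q15848
ADORA1	Adenosine receptor A1	P30542
ADORA2A	Adenosine receptor A2a	P29274
ADORA3	Adenosine receptor A3	P33765
ADRA1A	Alpha-1A adrenergic receptor	P35348
ADRA1B	Alpha-1B adrenergic receptor	P35368
ADRA1D	Alpha-1D adrenergic receptor	P25100
ADRB1	Beta-1 adrenergic receptor	P08588
ADRB2	Beta-2 adrenergic receptor	P07550
ADRB3	Beta-3 adrenergic receptor	P13945
ALDH2	Aldehyde dehydrogenase, mitochondrial	P05091
ALPI	Intestinal-type alkaline phosphatase	P09923
AMY1A	Alpha-amylase 1	P04745
AMY2A	Pancreatic alpha-amylase	P04746
AOC3	Membrane primary amine oxidase	Q16853
APP	Amyloid-beta A4 protein	P05067
AR	Androgen receptor	P10275
BCL6	B-cell lymphoma 6 protein	P41182
BDNF	Brain-derived neurotrophic factor	P23560
BMP2	Bone morphogenetic protein 2	P12643
CAMK2A	Calcium/calmodulin-dependent protein kinase type II subunit alpha	Q9UQM7
CAMK2B	Calcium/calmodulin-dependent protein kinase type II subunit beta	Q13554
CBR1	Carbonyl reductase [NADPH] 1	P16152
CCK	Cholecystokinin	P06307
CCL11	Eotaxin	P51671
CCL2	C-C motif chemokine 2	P13500
CCR4	C-C chemokine receptor type 4	P51679
CD80	T-lymphocyte activation antigen CD80	P33681
CELA1	Chymotrypsin-like elastase family member 1	Q9UNI1
CHRNA7	Neuronal acetylcholine receptor subunit alpha-7	P36544
CNR1	Cannabinoid receptor 1	P21554
CNR2	Cannabinoid receptor 2	P34972
CREB1	Cyclic AMP-responsive element-binding protein 1	P16220
CTSK	Cathepsin K	P43235
CYP1A2	Cytochrome P450 1A2	P05177
CYP2C19	Cytochrome P450 2C19	P33261
CYP3A4	Cytochrome P450 3A4	P08684
DPP4	Dipeptidyl peptidase 4	P27487
DRD2	D(2) dopamine receptor	P14416
DRD3	D(3) dopamine receptor	P35462
EGFR	Epidermal growth factor receptor	P00533
ESR1	Estrogen receptor	P03372
ESR2	Estrogen receptor beta	Q92731
FAAH	Fatty-acid amide hydrolase 1	O00519
FGF2	Fibroblast growth factor 2	P09038
FOS	Proto-oncogene c-Fos	P01100
FUT4	Alpha-(1,3)-fucosyltransferase 4	P22083
GABRA3	Gamma-aminobutyric acid receptor subunit alpha-3	P34903
GABRB3	Gamma-aminobutyric acid receptor subunit beta-3	P28472
GABRG2	Gamma-aminobutyric acid receptor subunit gamma-2	P18507
GHRL	Appetite-regulating hormone	Q9UBU3
GLO1	Lactoylglutathione lyase	Q9UBU3
GSK3B	Glycogen synthase kinase-3 beta	P49841
HDAC6	Histone deacetylase 6	Q9UBN7
HIF1A	Hypoxia-inducible factor 1-alpha	Q16665
HMOX1	Heme oxygenase 1	P09601
HTR3A	5-hydroxytryptamine receptor 3A	P46098
IGF2R	Cation-independent mannose-6-phosphate receptor	P11717
IL13	Interleukin-13	P35225
IL2	Interleukin-2	P60568
IL5	Interleukin-5	P05113
IL8	Interleukin-8	P10145
JUN	Transcription factor AP-1	P05412
KCNA3	Potassium voltage-gated channel subfamily A member 3	P22001
MAOA	Amine oxidase [flavin-containing] A	P21397
MAOB	Amine oxidase [flavin-containing] B	P27338
MAP2K7	Dual specificity mitogen-activated protein kinase kinase 7	O14733
MAP3K7	Mitogen-activated protein kinase kinase kinase 7	O43318
MAPK8	Mitogen-activated protein kinase 8	P45983
MAPT	Microtubule-associated protein tau	P10636
MCL1	Induced myeloid leukemia cell differentiation protein Mcl-1	Q07820
MMP1	22 kDa interstitial collagenase	P03956
MMP12	Macrophage metalloelastase	P39900
MMP9	67 kDa matrix metalloproteinase-9	P14780
NFKB1	Nuclear factor NF-kappa-B p105 subunit	P19838
NOS1	Nitric oxide synthase, brain	P29475
NOS2	Nitric oxide synthase, inducible	P35228
NOS3	Nitric oxide synthase, endothelial	P29474
NQO1	NAD(P)H dehydrogenase [quinone] 1	P15559
NR1I2	Nuclear receptor subfamily 1 group I member 2	O75469
NR4A2	Nuclear receptor subfamily 4 group A member 2	P43354
ODC1	Ornithine decarboxylase	P11926
OPRD1	Delta-type opioid receptor	P41143
OPRK1	Kappa-type opioid receptor	P41145
OPRL1	Nociceptin receptor	P41146
OPRM1	Mu-type opioid receptor	P35372
PARP1	Poly [ADP-ribose] polymerase 1	P09874
PDE11A	Dual 3′,5′-cyclic-AMP and -GMP phosphodiesterase 11A	Q9HCR9
PDE4A	cAMP-specific 3′,5′-cyclic phosphodiesterase 4A	P27815
PDE4D	cAMP-specific 3′,5′-cyclic phosphodiesterase 4D	Q08499
PIK3CA	Phosphatidylinositol 4,5-bisphosphate 3-kinase catalytic subunit alpha isoform	P42336
PIK3CG	Phosphatidylinositol 4,5-bisphosphate 3-kinase catalytic subunit gamma isoform	P48736
PLA2G1B	Phospholipase A2	P04054
PLAA	Phospholipase A-2-activating protein	Q9Y263
PLG	Plasmin light chain B	P00747
PPARD	Peroxisome proliferator-activated receptor delta	Q03181
PPARG	Peroxisome proliferator-activated receptor gamma	P37231
PRKCB	Protein kinase C beta type	P05771
PRKCG	Protein kinase C gamma type	P05129
PTGS1	Prostaglandin G/H synthase 1	P23219
PTGS2	Prostaglandin G/H synthase 2	P35354
RARA	Retinoic acid receptor alpha	P10276
REL	Proto-oncogene c-Rel	Q04864
RELA	Transcription factor p65	Q04206
SHBG	Sex hormone-binding globulin	P04278
SLC6A2	Sodium-dependent noradrenaline transporter	P23975
SLC6A3	Sodium-dependent dopamine transporter	Q01959
SLC6A4	Sodium-dependent serotonin transporter	P31645
SNCA	Alpha-synuclein	P37840
SRD5A1	3-oxo-5-alpha-steroid 4-dehydrogenase 1	P18405
STAT3	Signal transducer and activator of transcription 3	P40763
SYK	Tyrosine-protein kinase SYK	P43405
TACR1	Substance-P receptor	P25103
TACR2	Substance-K receptor	P21452
TACR3	Neuromedin-K receptor	P29371
TERT	Telomerase reverse transcriptase	O14746
TLR4	Toll-like receptor 4	O00206
TNFRSF1A	Tumor necrosis factor receptor superfamily member 1A	P19438
TNNI3	Troponin I, cardiac muscle	P19429
TP53	Cellular tumor antigen p53	P04637
TTR	Transthyretin	P02766
VDR	Vitamin D3 receptor	P11473
VEGFA	Vascular endothelial growth factor A	P15692
XDH	Xanthine dehydrogenase/oxidase	P47989
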