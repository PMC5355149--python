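symbol	gene_id	description	aliases
VEGFA	7422	vascular endothelial growth factor A	VEGF-A
AFP	174	alpha fetoprotein	alpha-fetoprotein
CDH1	999	cadherin 1	E-cadherin|ECAD
MMP2	4313	matrix metallopeptidase 2	MMP-2|gelatinase A
MMP9	4318	matrix metallopeptidase 9	MMP-9|gelatinase B
MAPK1	5594	mitogen-activated protein kinase 1	ERK2|ERK-2
TGFB1	7040	transforming growth factor beta 1	TGF-beta1
AKT1	207	AKT serine/threonine kinase 1	PKB-alpha
CTNNB1	1499	catenin beta 1	beta-catenin
PTK2	5747	protein tyrosine kinase 2	FAK|FAK1
SPP1	6696	secreted phosphoprotein 1	osteopontin|OPN
NME1	4830	NME nucleoside diphosphate kinase 1	NM23|NM23-H1
NFKB1	4790	nuclear factor kappa B subunit 1	NF-kappaB1
MET	4233	MET proto-oncogene receptor tyrosine kinase	c-Met
BSG	682	basigin	CD147|EMMPRIN
PIK3CA	5290	phosphatidylinositol-4,5-bisphosphate 3-kinase catalytic subunit alpha	p110alpha
HIF1A	3091	hypoxia inducible factor 1 subunit alpha	HIF-1alpha
CD44	960	CD44 molecule	CD44 antigen
FN1	2335	fibronectin 1	fibronectin
HGF	3082	hepatocyte growth factor	scatter factor
EGFR	1956	epidermal growth factor receptor	ErbB-1|HER1
TP53	7157	tumor protein p53	p53
MDM2	4193	MDM2 proto-oncogene	HDM2
UBC	7316	ubiquitin C	polyubiquitin-C
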