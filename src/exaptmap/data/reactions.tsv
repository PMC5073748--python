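id	kind	stoichiometry	lower_bound	upper_bound	name
ACALD	internal	acald_c:-1;accoa_c:1;coa_c:-1;h_c:1;nad_c:-1;nadh_c:1	-1000	1000	acetaldehyde dehydrogenase (acetylating)
ACKr	internal	ac_c:-1;actp_c:1;adp_c:1;atp_c:-1	-1000	1000	acetate kinase
ACONT	internal	cit_c:-1;icit_c:1	-1000	1000	Aconitase (A/B merged)
ADK1	internal	adp_c:2;amp_c:-1;atp_c:-1	-1000	1000	adenylate kinase
AKGDH	internal	akg_c:-1;co2_c:1;coa_c:-1;nad_c:-1;nadh_c:1;succoa_c:1	0	1000	2-Oxogluterate dehydrogenase
ATPM	internal	adp_c:1;atp_c:-1;h2o_c:-1;h_c:1;pi_c:1	0	1000	ATP maintenance requirement
ATPS4r	internal	adp_c:-1;atp_c:1;h2o_c:1;h_c:3;h_e:-4;pi_c:-1	-1000	1000	ATP synthase (four protons for one ATP)
CS	internal	accoa_c:-1;cit_c:1;coa_c:1;h2o_c:-1;h_c:1;oaa_c:-1	0	1000	citrate synthase
CYTBD	internal	h2o_c:1;h_c:-2;h_e:2;o2_c:-0.5;q8_c:1;q8h2_c:-1	0	1000	cytochrome oxidase bd (ubiquinol-8: 2 protons)
ENO	internal	2pg_c:-1;h2o_c:1;pep_c:1	-1000	1000	enolase
FBA	internal	dhap_c:1;fdp_c:-1;g3p_c:1	-1000	1000	fructose-bisphosphate aldolase
FBP	internal	f6p_c:1;fdp_c:-1;h2o_c:-1;pi_c:1	0	1000	fructose-bisphosphatase
FRD7	internal	fum_c:-1;q8_c:1;q8h2_c:-1;succ_c:1	0	1000	fumarate reductase
FUM	internal	fum_c:-1;h2o_c:-1;mal__L_c:1	-1000	1000	fumarase
G6PDH2r	internal	6pgl_c:1;g6p_c:-1;h_c:1;nadp_c:-1;nadph_c:1	-1000	1000	glucose 6-phosphate dehydrogenase
GAPD	internal	13dpg_c:1;g3p_c:-1;h_c:1;nad_c:-1;nadh_c:1;pi_c:-1	-1000	1000	glyceraldehyde-3-phosphate dehydrogenase
GLNS	internal	adp_c:1;atp_c:-1;gln__L_c:1;glu__L_c:-1;h_c:1;nh4_c:-1;pi_c:1	0	1000	glutamine synthetase
GLUDy	internal	akg_c:1;glu__L_c:-1;h2o_c:-1;h_c:1;nadp_c:-1;nadph_c:1;nh4_c:1	-1000	1000	glutamate dehydrogenase (NADP)
GLUN	internal	gln__L_c:-1;glu__L_c:1;h2o_c:-1;nh4_c:1	0	1000	glutaminase
GLUSy	internal	akg_c:-1;gln__L_c:-1;glu__L_c:2;h_c:-1;nadp_c:1;nadph_c:-1	0	1000	glutamate synthase (NADPH)
GND	internal	6pgc_c:-1;co2_c:1;nadp_c:-1;nadph_c:1;ru5p__D_c:1	0	1000	phosphogluconate dehydrogenase
ICDHyr	internal	akg_c:1;co2_c:1;icit_c:-1;nadp_c:-1;nadph_c:1	-1000	1000	isocitrate dehydrogenase (NADP)
ICL	internal	glx_c:1;icit_c:-1;succ_c:1	0	1000	Isocitrate lyase
LDH_D	internal	h_c:1;lac__D_c:-1;nad_c:-1;nadh_c:1;pyr_c:1	-1000	1000	D-lactate dehydrogenase
MALS	internal	accoa_c:-1;coa_c:1;glx_c:-1;h2o_c:-1;h_c:1;mal__L_c:1	0	1000	malate synthase
MDH	internal	h_c:1;mal__L_c:-1;nad_c:-1;nadh_c:1;oaa_c:1	-1000	1000	malate dehydrogenase
ME1	internal	co2_c:1;mal__L_c:-1;nad_c:-1;nadh_c:1;pyr_c:1	0	1000	malic enzyme (NAD)
ME2	internal	co2_c:1;mal__L_c:-1;nadp_c:-1;nadph_c:1;pyr_c:1	0	1000	malic enzyme (NADP)
NADH16	internal	h_c:-4;h_e:3;nad_c:1;nadh_c:-1;q8_c:-1;q8h2_c:1	0	1000	NADH dehydrogenase (ubiquinone-8 & 3 protons)
NADTRHD	internal	nad_c:-1;nadh_c:1;nadp_c:1;nadph_c:-1	0	1000	NAD transhydrogenase
PDH	internal	accoa_c:1;co2_c:1;coa_c:-1;nad_c:-1;nadh_c:1;pyr_c:-1	0	1000	pyruvate dehydrogenase
PFK	internal	adp_c:1;atp_c:-1;f6p_c:-1;fdp_c:1;h_c:1	0	1000	phosphofructokinase
PFL	internal	accoa_c:1;coa_c:-1;for_c:1;pyr_c:-1	0	1000	pyruvate formate lyase
PGI	internal	f6p_c:1;g6p_c:-1	-1000	1000	glucose-6-phosphate isomerase
PGK	internal	13dpg_c:1;3pg_c:-1;adp_c:1;atp_c:-1	-1000	1000	phosphoglycerate kinase
PGL	internal	6pgc_c:1;6pgl_c:-1;h2o_c:-1;h_c:1	0	1000	6-phosphogluconolactonase
PGM	internal	2pg_c:-1;3pg_c:1	-1000	1000	phosphoglycerate mutase
PPC	internal	co2_c:-1;h2o_c:-1;h_c:1;oaa_c:1;pep_c:-1;pi_c:1	0	1000	phosphoenolpyruvate carboxylase
PPCK	internal	adp_c:1;atp_c:-1;co2_c:1;oaa_c:-1;pep_c:1	0	1000	phosphoenolpyruvate carboxykinase
PPS	internal	amp_c:1;atp_c:-1;h2o_c:-1;h_c:2;pep_c:1;pi_c:1;pyr_c:-1	0	1000	phosphoenolpyruvate synthase
PTAr	internal	accoa_c:-1;actp_c:1;coa_c:1;pi_c:-1	-1000	1000	phosphotransacetylase
PYK	internal	adp_c:-1;atp_c:1;h_c:-1;pep_c:-1;pyr_c:1	0	1000	pyruvate kinase
RPE	internal	ru5p__D_c:-1;xu5p__D_c:1	-1000	1000	ribulose 5-phosphate 3-epimerase
RPI	internal	r5p_c:-1;ru5p__D_c:1	-1000	1000	ribose-5-phosphate isomerase
SUCDi	internal	fum_c:1;q8_c:-1;q8h2_c:1;succ_c:-1	0	1000	succinate dehydrogenase (irreversible)
SUCOAS	internal	adp_c:1;atp_c:-1;coa_c:-1;pi_c:1;succ_c:-1;succoa_c:1	-1000	1000	succinyl-CoA synthetase (ADP-forming)
TALA	internal	e4p_c:1;f6p_c:1;g3p_c:-1;s7p_c:-1	-1000	1000	transaldolase
THD2	internal	h_c:2;h_e:-2;nad_c:1;nadh_c:-1;nadp_c:-1;nadph_c:1	0	1000	R NAD - P-transhydrogenase
TKT1	internal	g3p_c:1;r5p_c:-1;s7p_c:1;xu5p__D_c:-1	-1000	1000	transketolase
TKT2	internal	e4p_c:-1;f6p_c:1;g3p_c:1;xu5p__D_c:-1	-1000	1000	transketolase
TPI	internal	dhap_c:-1;g3p_c:1	-1000	1000	triose-phosphate isomerase
ACALDt	transport	acald_c:1;acald_e:-1	-1000	1000	R acetaldehyde reversible - transport
ACt2r	transport	ac_c:1;ac_e:-1;h_c:1;h_e:-1	-1000	1000	R acetate reversible transport via proton - symport
AKGt2r	transport	akg_c:1;akg_e:-1;h_c:1;h_e:-1	-1000	1000	R 2 oxoglutarate reversible transport via - symport
CO2t	transport	co2_c:1;co2_e:-1	-1000	1000	R CO2 transporter via - diffusion
D_LACt2	transport	h_c:1;h_e:-1;lac__D_c:1;lac__D_e:-1	-1000	1000	R D lactate transport via proton - symport
FORt2	transport	for_c:1;for_e:-1;h_c:1;h_e:-1	0	1000	formate transport in via proton symport
FORti	transport	for_c:-1;for_e:1	0	1000	formate transport via diffusion
FRUpts2	transport	f6p_c:1;fru_e:-1;pep_c:-1;pyr_c:1	0	1000	R Fructose transport via PEPPyr PTS-f6p - generating
FUMt2_2	transport	fum_c:1;fum_e:-1;h_c:2;h_e:-2	0	1000	R Fumarate transport via proton symport-2 - H
GLCpts	transport	g6p_c:1;glc__D_e:-1;pep_c:-1;pyr_c:1	0	1000	D-glucose transport via PEP:Pyr PTS
GLNabc	transport	adp_c:1;atp_c:-1;gln__L_c:1;gln__L_e:-1;h2o_c:-1;h_c:1;pi_c:1	0	1000	GLNabc
GLUt2r	transport	glu__L_c:1;glu__L_e:-1;h_c:1;h_e:-1	-1000	1000	R L glutamate transport via proton - symport-reversible
H2Ot	transport	h2o_c:1;h2o_e:-1	-1000	1000	R H2O transport via - diffusion
MALt2_2	transport	h_c:2;h_e:-2;mal__L_c:1;mal__L_e:-1	0	1000	R Malate transport via proton symport-2 - H
NH4t	transport	nh4_c:1;nh4_e:-1	-1000	1000	R ammonia reversible - transport
O2t	transport	o2_c:1;o2_e:-1	-1000	1000	R o2 - transport-diffusion
PIt2r	transport	h_c:1;h_e:-1;pi_c:1;pi_e:-1	-1000	1000	R phosphate reversible transport via - symport
PYRt2	transport	h_c:1;h_e:-1;pyr_c:1;pyr_e:-1	-1000	1000	R pyruvate transport in via proton - symport
SUCCt2_2	transport	h_c:2;h_e:-2;succ_c:1;succ_e:-1	0	1000	R succinate transport via proton symport-2 - H
SUCCt3	transport	h_c:1;h_e:-1;succ_c:-1;succ_e:1	0	1000	succinate transport out via proton antiport
EX_ac_e	exchange	ac_e:-1	0	1000	Acetate exchange
EX_akg_e	exchange	akg_e:-1	0	1000	2-Oxoglutarate exchange
EX_co2_e	exchange	co2_e:-1	0	1000	CO2 exchange
EX_for_e	exchange	for_e:-1	0	1000	Formate exchange
EX_fru_e	exchange	fru_e:-1	0	1000	D-Fructose exchange
EX_fum_e	exchange	fum_e:-1	0	1000	Fumarate exchange
EX_glc__D_e	exchange	glc__D_e:-1	0	1000	D-Glucose exchange
EX_gln__L_e	exchange	gln__L_e:-1	0	1000	L-Glutamine exchange
EX_glu__L_e	exchange	glu__L_e:-1	0	1000	L-Glutamate exchange
EX_h2o_e	exchange	h2o_e:-1	0	1000	H2O exchange
EX_h_e	exchange	h_e:-1	0	1000	H+ exchange
EX_lac__D_e	exchange	lac__D_e:-1	0	1000	D-lactate exchange
EX_mal__L_e	exchange	mal__L_e:-1	0	1000	L-Malate exchange
EX_nh4_e	exchange	nh4_e:-1	0	1000	Ammonia exchange
EX_o2_e	exchange	o2_e:-1	0	1000	O2 exchange
EX_pi_e	exchange	pi_e:-1	0	1000	Phosphate exchange
EX_pyr_e	exchange	pyr_e:-1	0	1000	Pyruvate exchange
EX_succ_e	exchange	succ_e:-1	0	1000	Succinate exchange
Biomass	biomass	3pg_c:-1.496;accoa_c:-3.7478;adp_c:59.81;akg_c:4.1182;atp_c:-59.81;coa_c:3.7478;e4p_c:-0.361;f6p_c:-0.0709;g3p_c:-0.129;g6p_c:-0.205;gln__L_c:-0.2557;glu__L_c:-4.9414;h2o_c:-59.81;h_c:59.81;nad_c:-3.547;nadh_c:3.547;nadp_c:13.0279;nadph_c:-13.0279;oaa_c:-1.7867;pep_c:-0.5191;pi_c:59.81;pyr_c:-2.8328;r5p_c:-0.8977	0	1000	Biomass Objective Function with GAM
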