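id	name	external	biomass_precursor	carbon_atoms
13dpg_c	3-Phospho-D-glyceroyl phosphate	0	0	3
2pg_c	D-Glycerate 2-phosphate	0	0	3
3pg_c	3-Phospho-D-glycerate	0	1	3
6pgc_c	6-Phospho-D-gluconate	0	0	6
6pgl_c	6-phospho-D-glucono-1,5-lactone	0	0	6
ac_c	Acetate	0	0	2
ac_e	Acetate	1	0	2
acald_c	Acetaldehyde	0	0	2
acald_e	Acetaldehyde	1	0	2
accoa_c	Acetyl-CoA	0	1	23
actp_c	Acetyl phosphate	0	0	2
adp_c	ADP	0	0	10
akg_c	2-Oxoglutarate	0	1	5
akg_e	2-Oxoglutarate	1	0	5
amp_c	AMP	0	0	10
atp_c	ATP	0	0	10
cit_c	Citrate	0	0	6
co2_c	CO2	0	0	1
co2_e	CO2	1	0	1
coa_c	Coenzyme A	0	0	21
dhap_c	Dihydroxyacetone phosphate	0	0	3
e4p_c	D-Erythrose 4-phosphate	0	1	4
f6p_c	D-Fructose 6-phosphate	0	1	6
fdp_c	D-Fructose 1,6-bisphosphate	0	0	6
for_c	Formate	0	0	1
for_e	Formate	1	0	1
fru_e	D-Fructose	1	0	6
fum_c	Fumarate	0	0	4
fum_e	Fumarate	1	0	4
g3p_c	Glyceraldehyde 3-phosphate	0	1	3
g6p_c	D-Glucose 6-phosphate	0	1	6
glc__D_e	D-Glucose	1	0	6
gln__L_c	L-Glutamine	0	1	5
gln__L_e	L-Glutamine	1	0	5
glu__L_c	L-Glutamate	0	1	5
glu__L_e	L-Glutamate	1	0	5
glx_c	Glyoxylate	0	0	2
h2o_c	H2O	0	0	0
h2o_e	H2O	1	0	0
h_c	H+	0	0	0
h_e	H+	1	0	0
icit_c	Isocitrate	0	0	6
lac__D_c	D-Lactate	0	0	3
lac__D_e	D-Lactate	1	0	3
mal__L_c	L-Malate	0	0	4
mal__L_e	L-Malate	1	0	4
nad_c	Nicotinamide adenine dinucleotide	0	0	21
nadh_c	Nicotinamide adenine dinucleotide - reduced	0	0	21
nadp_c	Nicotinamide adenine dinucleotide phosphate	0	0	21
nadph_c	Nicotinamide adenine dinucleotide phosphate - reduced	0	0	21
nh4_c	Ammonium	0	0	0
nh4_e	Ammonium	1	0	0
o2_c	O2	0	0	0
o2_e	O2	1	0	0
oaa_c	Oxaloacetate	0	1	4
pep_c	Phosphoenolpyruvate	0	1	3
pi_c	Phosphate	0	0	0
pi_e	Phosphate	1	0	0
pyr_c	Pyruvate	0	1	3
pyr_e	Pyruvate	1	0	3
q8_c	Ubiquinone-8	0	0	49
q8h2_c	Ubiquinol-8	0	0	49
r5p_c	alpha-D-Ribose 5-phosphate	0	1	5
ru5p__D_c	D-Ribulose 5-phosphate	0	0	5
s7p_c	Sedoheptulose 7-phosphate	0	0	7
succ_c	Succinate	0	0	4
succ_e	Succinate	1	0	4
succoa_c	Succinyl-CoA	0	0	25
xu5p__D_c	D-Xylulose 5-phosphate	0	0	5
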