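{
  "carbon_uptake_bound": 10.0,
  "nutrient_bound": 1000.0,
  "fixed_nutrients": [
    "nh4_e",
    "pi_e",
    "o2_e",
    "h_e",
    "h2o_e"
  ],
  "sources": {
    "acetate": "ac_e",
    "alpha_ketoglutarate": "akg_e",
    "fructose": "fru_e",
    "fumarate": "fum_e",
    "glucose": "glc__D_e",
    "glutamate": "glu__L_e",
    "lactate": "lac__D_e",
    "malate": "mal__L_e",
    "pyruvate": "pyr_e",
    "succinate": "succ_e"
  }
}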