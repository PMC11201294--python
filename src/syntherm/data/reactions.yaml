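# Default reactions for syntrophic acid oxidation and methanogenesis.
# Coefficients are signed: reactants negative, products positive.
acetate_oxidation:
  reference: "CH3COO- + H+ + 2 H2O -> 2 CO2 + 4 H2"
  stoichiometry:
    acetate: -1
    H+: -1
    H2O: -2
    CO2: 2
    H2: 4
propionate_oxidation:
  reference: "CH3CH2COO- + 2 H2O -> CH3COO- + CO2 + 3 H2"
  stoichiometry:
    propionate: -1
    H2O: -2
    acetate: 1
    CO2: 1
    H2: 3
hydrogenotrophic_methanogenesis:
  reference: "4 H2 + CO2 -> CH4 + 2 H2O"
  stoichiometry:
    H2: -4
    CO2: -1
    CH4: 1
    H2O: 2
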