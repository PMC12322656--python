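# Physical constants used across the package.  Plain "key = value" pairs;
# lines starting with '#' are comments.  A trailing "suspect" marker flags
# printed values that are internally inconsistent in the source report.

# Enzyme subunit molar masses (g/mol)
ppnn_wt_subunit_mass = 51794
ry_subunit_mass = 51440
yein_subunit_mass = 32909

# Molar extinction coefficients for HPLC/UV quantification (1/(mM cm))
eps_ura_258nm = 8.3
eps_ump_262nm = 10.0
eps_psimp_262nm = 7.5

# Protein A280 coefficients (1/(M cm)).  The same value is printed for both
# YeiN and PpnN/RY, almost certainly a copy error for PpnN/RY.
eps280_yein = 10095
eps280_ppnn = 10095  suspect

# Compound molar masses (g/mol)
psimp_disodium_mass = 368.15
psimp_free_acid_mass = 324.18
ump_disodium_mass = 368.15
pseudouridine_mass = 244.20
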