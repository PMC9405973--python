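# Energetic constants of the surface-area / entropy parameterization.
# alpha, beta: heat-capacity coefficients of buried apolar/polar surface
# (cal K^-1 mol^-1 A^-2); f_ap: average interface hydrophobicity; Ts:
# solvation reference temperature (K); dS_rt: roto-translational entropy of
# a bimolecular association (cal mol^-1 K^-1); asa_per_residue (A^2) and
# dS_per_rotor (cal mol^-1 K^-1) convert conformational terms into residue
# and rotatable-bond counts.
[energetic]
gas_constant = 1.9872
Ts = 385.15
dS_rt = -8.0
alpha = 0.45
beta = -0.26
f_ap = 0.68
asa_per_residue = 47.0
dS_per_rotor = 1.7

# Rigid-body heat-capacity change (cal mol^-1 K^-1) of each GTPase-ligand
# complex, from surface-area calculations on the complex structures; taken
# as inputs here, keyed "LIGAND:mg_state".
[dcp_rb]
"GTP:+Mg" = -25.0
"GTP:-Mg" = -11.0
"GDP:+Mg" = -48.0
"GDP:-Mg" = -30.0

# Mg(2+)-nucleotide association constants (M^-1) and stepwise enthalpies
# (kcal mol^-1).  PLACEHOLDER literature-style magnitudes: override with
# condition-specific values (ionic strength, pH) when available.
[mg_binding]
K_MgGTP = 1.0e4
K_MgGDP = 3.1623e3
K_Mg2GTP = 1.0e2
K_Mg2GDP = 0.0
dH_MgGTP = 0.0
dH_MgGDP = 0.0
dH_Mg2GTP = 0.0
dH_Mg2GDP = 0.0
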