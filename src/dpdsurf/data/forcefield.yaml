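# DPD force field for alkyl ethoxylate (CnEm) surfactants in water at 25 C.
# Reduced units: r_c = 1 (water self-cutoff), k_B*T = 1, bead mass = 1.
#
# The "revised" tables are the bit-exact parameter set of the model; the
# "original" override section restores the antecedent parameterisation
# (alkyl-ether A_ij = 28.5, all angles theta0 = 180 deg with k_a = 5).
#
# angle_extensions: triplets that occur in parameterised solutes (octanol,
# diethyl ether, 2-hexyloxyethanol) and short-head CnEm but are not part of
# the core angle table. Each mirrors the closest terminal-analog core entry
# (see docs/methods.md). Strict lookups can exclude them.

model: cnem-dpd-25C
gamma: 4.5

beads:
  # name: [heavy_atom_count, self_cutoff R_ii, hydrophobic]
  2H2O:    [2, 1.0000, false]
  CH3:     [1, 0.9570, true]
  CH2CH2:  [2, 1.0740, true]
  CH2OCH2: [3, 1.1160, false]
  CH2OH:   [2, 0.9800, false]

bond:
  k_b: 150.0
  # r_0 = 0.1*(n_i + n_j) - 0.01 with n the heavy-atom counts

pairs:
  # [bead_i, bead_j, A_ij, R_ij]
  - [2H2O,    2H2O,    25.0, 1.0000]
  - [2H2O,    CH2CH2,  45.0, 1.0370]
  - [2H2O,    CH3,     45.0, 0.9785]
  - [2H2O,    CH2OCH2, 24.0, 1.0580]
  - [2H2O,    CH2OH,   14.5, 0.9900]
  - [CH2CH2,  CH2CH2,  22.0, 1.0740]
  - [CH2CH2,  CH3,     23.0, 1.0155]
  - [CH2CH2,  CH2OCH2, 24.2, 1.0950]
  - [CH2CH2,  CH2OH,   26.0, 1.0270]
  - [CH3,     CH3,     24.0, 0.9570]
  - [CH3,     CH2OCH2, 24.2, 1.0365]
  - [CH3,     CH2OH,   26.0, 0.9685]
  - [CH2OCH2, CH2OCH2, 25.5, 1.1160]
  - [CH2OCH2, CH2OH,   25.0, 1.0480]
  - [CH2OH,   CH2OH,   14.0, 0.9800]

angles:
  # [bead_i, bead_j, bead_k, k_a, theta0_deg]  (j is the apex bead)
  - [CH3,     CH2CH2,  CH2CH2,  30, 180]
  - [CH2CH2,  CH2CH2,  CH2CH2,  30, 180]
  - [CH2CH2,  CH2CH2,  CH2OCH2, 15, 180]
  - [CH2CH2,  CH2OCH2, CH2OCH2, 15, 145]
  - [CH2OCH2, CH2OCH2, CH2OCH2, 15, 132]
  - [CH2OCH2, CH2OCH2, CH2OH,   15, 145]

angle_extensions:
  - [CH3,     CH2CH2,  CH2OCH2, 15, 180]   # terminal analog of CC-CC-E
  - [CH2CH2,  CH2CH2,  CH2OH,   15, 180]   # terminal analog of CC-CC-E
  - [CH2CH2,  CH2OCH2, CH2OH,   15, 145]   # terminal analog of CC-E-E / E-E-OH
  - [CH3,     CH2OCH2, CH3,     15, 145]   # diethyl ether C-O-C apex

original_overrides:
  pairs:
    - [CH2CH2, CH2OCH2, 28.5]
    - [CH3,    CH2OCH2, 28.5]
  angles_all: {k_a: 5, theta0_deg: 180}
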