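# Default body-segment parameter table for the segmental CoM method.
#
# Columns:
#   name, side          segment label and body side (C = central)
#   proximal_idx        BODY_25 index of the proximal joint
#   distal_idx          BODY_25 index of the distal joint
#   mass_fraction_male  segment mass as a fraction of total body mass (males)
#   mass_fraction_female  same for females
#   k_male, k_female    proximal CoM coefficient: the segment CoM sits at
#                       fraction k of the way from the proximal to the distal
#                       joint, measured from the proximal end
#
# Mass fractions are the Plagenhoef (1983) water-immersion statistics
# (per-limb values; whole-body set sums to 100% for each sex).  The k values
# for forearm, upper arm and trunk are the sex-specific Plagenhoef locations
# used throughout this package (M: 0.430/0.436/0.630, F: 0.434/0.458/0.569);
# the head+neck k is a package default from standard anthropometric tables.
# The trunk is measured hip joint (MidHip) -> shoulder line (Neck), the full
# hip-to-shoulder distance being 100% of trunk length.
#
# The default modeled set is the upper body above the hip joint.  BODY_25 has
# no distal hand landmark, so hand mass is not modeled (see docs/methods.md).
segments:
  - {name: trunk,      side: C, proximal_idx: 8, distal_idx: 1,
     mass_fraction_male: 0.4684, mass_fraction_female: 0.4500,
     k_male: 0.630, k_female: 0.569}
  - {name: head_neck,  side: C, proximal_idx: 1, distal_idx: 0,
     mass_fraction_male: 0.0826, mass_fraction_female: 0.0820,
     k_male: 0.550, k_female: 0.550}
  - {name: upper_arm,  side: R, proximal_idx: 2, distal_idx: 3,
     mass_fraction_male: 0.0325, mass_fraction_female: 0.0290,
     k_male: 0.436, k_female: 0.458}
  - {name: upper_arm,  side: L, proximal_idx: 5, distal_idx: 6,
     mass_fraction_male: 0.0325, mass_fraction_female: 0.0290,
     k_male: 0.436, k_female: 0.458}
  - {name: forearm,    side: R, proximal_idx: 3, distal_idx: 4,
     mass_fraction_male: 0.0187, mass_fraction_female: 0.0157,
     k_male: 0.430, k_female: 0.434}
  - {name: forearm,    side: L, proximal_idx: 6, distal_idx: 7,
     mass_fraction_male: 0.0187, mass_fraction_female: 0.0157,
     k_male: 0.430, k_female: 0.434}
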