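# Material library, SI units (Pa, kg/m^3).
# Probe materials: supplier-provided linear-elastic constants.
# brain_tissue: first-order Ogden set for adult rodent hippocampus (CA3SR);
#   mu interpreted in Pa (mu0 = mu1*alpha1/2 ~ 63.6 Pa); the volumetric
#   penalty defaults to 1e5 * mu0 when omitted.
steel:
  model: linear_elastic
  youngs_modulus: 1.93e+11
  poissons_ratio: 0.25
  density: 7990.0
silica:
  model: linear_elastic
  youngs_modulus: 6.63e+10
  poissons_ratio: 0.15
  density: 2170.0
PC:
  model: linear_elastic
  youngs_modulus: 2.30e+9
  poissons_ratio: 0.37
  density: 1200.0
hydrogel:
  model: linear_elastic
  youngs_modulus: 3.76e+6
  poissons_ratio: 0.46
  density: 1080.0
brain_tissue:
  model: ogden
  mu: [8.1]
  alpha: [15.7]
  density: 1040.0
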