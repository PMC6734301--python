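# Default CT calibration ramp: node materials with Hounsfield unit,
# physical density [g/cm^3], mass stopping power ratio to water (mSPR)
# and the empirical CSDA range coefficient a_csda [cm/MeV^2].
# scatter_ratio is the multiple-scattering strength per unit mass relative
# to water, X0(water) / X0(material) with X0 in g/cm^2: high-Z mineralized
# tissues scatter considerably more per g/cm^2 than soft tissue.
# HU values between nodes define mixed materials by linear interpolation.
materials:
  - {name: air,           hu: -1000, density: 0.00125, mspr: 0.88, a_csda: 0.765,    scatter_ratio: 0.985}
  - {name: lung,          hu: -610,  density: 0.384,   mspr: 0.99, a_csda: 0.002640, scatter_ratio: 1.00}
  - {name: adipose,       hu: -77,   density: 0.95,    mspr: 1.03, a_csda: 0.001019, scatter_ratio: 0.93}
  - {name: muscle,        hu: 40,    density: 1.05,    mspr: 1.00, a_csda: 0.000963, scatter_ratio: 0.99}
  - {name: spongiosa,     hu: 102,   density: 1.1,     mspr: 0.99, a_csda: 0.000920, scatter_ratio: 1.20}
  - {name: cortical_bone, hu: 1524,  density: 1.92,    mspr: 0.89, a_csda: 0.000608, scatter_ratio: 2.17}
  - {name: teeth,         hu: 3055,  density: 2.75,    mspr: 0.86, a_csda: 0.000445, scatter_ratio: 2.55}
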