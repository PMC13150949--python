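{
  "name": "SixFactorSynthetic",
  "synthetic": true,
  "description": "SYNTHETIC six-factor amino-acid descriptor set. It mirrors the factor semantics of published factor-analysis descriptor sets (F1 hydrophobicity, F2 alpha/turn propensity, F3 bulk, F4 composition, F5 local flexibility, F6 electronic properties) but is constructed in-package by z-scoring six classical single-property scales over the 20 standard residues. It is NOT the published factor-analysis matrix; factor values are proxies with the same sign conventions and are suitable for method development and simulation-based testing only.",
  "factor_names": ["F1", "F2", "F3", "F4", "F5", "F6"],
  "base_scales": {
    "F1_hydropathy_kyte_doolittle": {
      "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
      "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
      "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
      "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2
    },
    "F2_helix_propensity_chou_fasman": {
      "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70,
      "Q": 1.11, "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08,
      "L": 1.21, "K": 1.16, "M": 1.45, "F": 1.13, "P": 0.57,
      "S": 0.77, "T": 0.83, "W": 1.08, "Y": 0.69, "V": 1.06
    },
    "F3_residue_volume_A3": {
      "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
      "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
      "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
      "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0
    },
    "F4_residue_mass_Da": {
      "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
      "Q": 128.13, "E": 129.12, "G": 57.05, "H": 137.14, "I": 113.16,
      "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
      "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13
    },
    "F5_sidechain_rotatable_bonds": {
      "A": 0, "R": 5, "N": 2, "D": 2, "C": 1,
      "Q": 3, "E": 3, "G": 0, "H": 2, "I": 2,
      "L": 2, "K": 4, "M": 3, "F": 2, "P": 0,
      "S": 1, "T": 1, "W": 2, "Y": 2, "V": 1
    },
    "F6_sidechain_charge_pH7_lehninger": {
      "A": 0.0, "R": 0.99997, "N": 0.0, "D": -0.99955, "C": -0.06196,
      "Q": 0.0, "E": -0.99822, "G": 0.0, "H": 0.09091, "I": 0.0,
      "L": 0.0, "K": 0.99971, "M": 0.0, "F": 0.0, "P": 0.0,
      "S": 0.0, "T": 0.0, "W": 0.0, "Y": -0.00085, "V": 0.0
    }
  }
}
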