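# Lipid-class catalog configuration.
#
# Each class gives the linear formula rule (element: [const, per_carbon,
# per_double_bond]), the sum-composition grid, the adduct set per the
# ionization mode the class is routinely measured in, and the spiked
# internal standard (amount in nmol per 20 uL plasma extraction).
#
# Formula rules are the unique sum-composition rules consistent with the
# class backbone plus fatty-acyl condensation, validated against the named
# internal standards (e.g. PC(14:0/14:0) = C36H72NO8P). For sphingolipids
# (SM, Cer) the double-bond count includes the sphingoid 4,5-ene.

adducts:
  positive: ["[M+H]+", "[M+NH4]+", "[M+Na]+"]
  negative: ["[M-H]-", "[M+HCOO]-"]

classes:
  LPC:
    radyl_count: 1
    formula: {C: [8, 1, 0], H: [18, 2, -2], N: [1, 0, 0], O: [7, 0, 0], P: [1, 0, 0]}
    carbon_range: [10, 30]
    db_range: [0, 12]
    adducts: ["[M+H]+", "[M+Na]+"]
    internal_standard: {species: "LPC(14:0)", amount_nmol: 0.5, plasma_volume_ul: 20.0}
  PC:
    radyl_count: 2
    formula: {C: [8, 1, 0], H: [16, 2, -2], N: [1, 0, 0], O: [8, 0, 0], P: [1, 0, 0]}
    carbon_range: [20, 60]
    db_range: [0, 12]
    adducts: ["[M+H]+", "[M+Na]+"]
    internal_standard: {species: "PC(14:0/14:0)", amount_nmol: 2.0, plasma_volume_ul: 20.0}
  LPE:
    radyl_count: 1
    formula: {C: [5, 1, 0], H: [12, 2, -2], N: [1, 0, 0], O: [7, 0, 0], P: [1, 0, 0]}
    carbon_range: [10, 30]
    db_range: [0, 12]
    adducts: ["[M-H]-"]
    internal_standard: {species: "LPE(14:0)", amount_nmol: 0.1, plasma_volume_ul: 20.0}
  PE:
    radyl_count: 2
    formula: {C: [5, 1, 0], H: [10, 2, -2], N: [1, 0, 0], O: [8, 0, 0], P: [1, 0, 0]}
    carbon_range: [20, 60]
    db_range: [0, 12]
    adducts: ["[M-H]-"]
    internal_standard: {species: "PE(14:0/14:0)", amount_nmol: 0.5, plasma_volume_ul: 20.0}
  LPG:
    radyl_count: 1
    formula: {C: [6, 1, 0], H: [13, 2, -2], O: [9, 0, 0], P: [1, 0, 0]}
    carbon_range: [10, 30]
    db_range: [0, 12]
    adducts: ["[M-H]-"]
    internal_standard: {species: "LPG(14:0)", amount_nmol: 0.02, plasma_volume_ul: 20.0}
  PG:
    radyl_count: 2
    formula: {C: [6, 1, 0], H: [11, 2, -2], O: [10, 0, 0], P: [1, 0, 0]}
    carbon_range: [20, 60]
    db_range: [0, 12]
    adducts: ["[M-H]-"]
    internal_standard: {species: "PG(14:0/14:0)", amount_nmol: 0.1, plasma_volume_ul: 20.0}
  LPA:
    radyl_count: 1
    formula: {C: [3, 1, 0], H: [7, 2, -2], O: [7, 0, 0], P: [1, 0, 0]}
    carbon_range: [10, 30]
    db_range: [0, 12]
    adducts: ["[M-H]-"]
    internal_standard: {species: "LPA(14:0)", amount_nmol: 0.1, plasma_volume_ul: 20.0}
  PA:
    radyl_count: 2
    formula: {C: [3, 1, 0], H: [5, 2, -2], O: [8, 0, 0], P: [1, 0, 0]}
    carbon_range: [20, 60]
    db_range: [0, 12]
    adducts: ["[M-H]-"]
    internal_standard: {species: "PA(14:0/14:0)", amount_nmol: 0.5, plasma_volume_ul: 20.0}
  PI:
    radyl_count: 2
    formula: {C: [9, 1, 0], H: [15, 2, -2], O: [13, 0, 0], P: [1, 0, 0]}
    carbon_range: [20, 60]
    db_range: [0, 12]
    adducts: ["[M-H]-"]
    internal_standard: {species: "PI(8:0/8:0)", amount_nmol: 0.5, plasma_volume_ul: 20.0}
  PS:
    radyl_count: 2
    formula: {C: [6, 1, 0], H: [10, 2, -2], N: [1, 0, 0], O: [10, 0, 0], P: [1, 0, 0]}
    carbon_range: [20, 60]
    db_range: [0, 12]
    adducts: ["[M-H]-"]
    internal_standard: {species: "PS(14:0/14:0)", amount_nmol: 5.0, plasma_volume_ul: 20.0}
  CL:
    radyl_count: 4
    formula: {C: [9, 1, 0], H: [14, 2, -2], O: [17, 0, 0], P: [2, 0, 0]}
    carbon_range: [40, 80]
    db_range: [0, 12]
    adducts: ["[M-H]-"]
    internal_standard: {species: "CL(14:0/14:0/14:0/14:0)", amount_nmol: 0.1, plasma_volume_ul: 20.0}
  DG:
    radyl_count: 2
    formula: {C: [3, 1, 0], H: [4, 2, -2], O: [5, 0, 0]}
    carbon_range: [20, 60]
    db_range: [0, 12]
    adducts: ["[M+NH4]+", "[M+Na]+"]
    internal_standard: {species: "DG(14:0/14:0)", amount_nmol: 0.5, plasma_volume_ul: 20.0}
  TG:
    radyl_count: 3
    formula: {C: [3, 1, 0], H: [2, 2, -2], O: [6, 0, 0]}
    carbon_range: [30, 80]
    db_range: [0, 12]
    adducts: ["[M+NH4]+", "[M+Na]+"]
    internal_standard: {species: "TG(14:0/14:0/14:0)", amount_nmol: 0.5, plasma_volume_ul: 20.0}
  CE:
    radyl_count: 1
    formula: {C: [27, 1, 0], H: [44, 2, -2], O: [2, 0, 0]}
    carbon_range: [10, 30]
    db_range: [0, 12]
    adducts: ["[M+NH4]+", "[M+Na]+"]
    internal_standard: {species: "D7-CE(16:0)", amount_nmol: 2.5, plasma_volume_ul: 20.0}
  SM:
    radyl_count: 2
    formula: {C: [5, 1, 0], H: [13, 2, -2], N: [2, 0, 0], O: [6, 0, 0], P: [1, 0, 0]}
    carbon_range: [20, 60]
    db_range: [0, 12]
    adducts: ["[M+H]+", "[M+Na]+"]
    internal_standard: {species: "SM(d18:1/12:0)", amount_nmol: 2.125, plasma_volume_ul: 20.0}
  Cer:
    radyl_count: 2
    formula: {C: [0, 1, 0], H: [1, 2, -2], N: [1, 0, 0], O: [3, 0, 0]}
    carbon_range: [20, 60]
    db_range: [0, 12]
    adducts: ["[M+H]+"]
    # spiked as part of a sphingosine/ceramide mixture
    internal_standard: {species: "Cer(d18:1/12:0)", amount_nmol: 0.125, plasma_volume_ul: 20.0}
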