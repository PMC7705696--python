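# Preset materials for neutron contrast planning in wood/PEG systems.
#
# Densities are documented approximations taken from standard handbook
# values for the wet-wall phases: crystalline cellulose I-beta 1.60 g/cm3,
# milled-wood lignin ~1.40 g/cm3 (C9H10O3 softwood monomer approximation),
# amorphous PEG repeat unit 1.13 g/cm3, D2O 1.105 g/cm3, H2O 0.997 g/cm3.
# n_exchangeable_H counts labile (OH/NH) hydrogens per formula unit that
# equilibrate with the solvent.
cellulose:
  formula: {C: 6, H: 10, O: 5}
  mass_density: 1.60
  n_exchangeable_H: 3
lignin:
  formula: {C: 9, H: 10, O: 3}
  mass_density: 1.40
  n_exchangeable_H: 1
peg:
  formula: {C: 2, H: 4, O: 1}
  mass_density: 1.13
  n_exchangeable_H: 0
d2o:
  formula: {D: 2, O: 1}
  mass_density: 1.105
  n_exchangeable_H: 0
h2o:
  formula: {H: 2, O: 1}
  mass_density: 0.997
  n_exchangeable_H: 2
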