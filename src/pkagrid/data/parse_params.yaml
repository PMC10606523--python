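# PARSE-style united-heavy-atom charge/radius table, version 1.
#
# Hydrogen partial charges are folded into the bonded heavy atom so that
# hydrogen-free structures carry the full formal charge of each residue.
# Radii are Pauling-type van der Waals radii by element (overridable per atom).
# Titratable residues carry both protonation variants; the difference
# (protonated - deprotonated) sums to exactly +1 e over variant_atoms.
version: 1
radii_by_element:
  C: 1.70
  N: 1.50
  O: 1.40
  S: 1.85
  H: 1.00
backbone:
  N: 0.0
  CA: 0.0
  C: 0.55
  O: -0.55
# Applied when a terminal carboxylate oxygen OXT is present: the terminal
# COO- group replaces the backbone C/O charges of that residue.
cter_patch:
  deprotonated: {C: 0.10, O: -0.55, OXT: -0.55}
  protonated: {C: 0.20, O: -0.30, OXT: 0.10}
  model_pka: 3.8
nter_patch:
  protonated: {N: 1.0}
  deprotonated: {N: 0.0}
  model_pka: 7.5
residues:
  ALA: {formal_charge: 0, atoms: {CB: 0.0}}
  GLY: {formal_charge: 0, atoms: {}}
  VAL: {formal_charge: 0, atoms: {CB: 0.0, CG1: 0.0, CG2: 0.0}}
  LEU: {formal_charge: 0, atoms: {CB: 0.0, CG: 0.0, CD1: 0.0, CD2: 0.0}}
  ILE: {formal_charge: 0, atoms: {CB: 0.0, CG1: 0.0, CG2: 0.0, CD1: 0.0}}
  PRO: {formal_charge: 0, atoms: {CB: 0.0, CG: 0.0, CD: 0.0}}
  PHE: {formal_charge: 0, atoms: {CB: 0.0, CG: 0.0, CD1: 0.0, CD2: 0.0, CE1: 0.0, CE2: 0.0, CZ: 0.0}}
  MET: {formal_charge: 0, atoms: {CB: 0.0, CG: 0.0, SD: 0.0, CE: 0.0}}
  TRP:
    formal_charge: 0
    atoms: {CB: 0.0, CG: 0.0, CD1: 0.0, CD2: 0.0, NE1: 0.0, CE2: 0.0, CE3: 0.0, CZ2: 0.0, CZ3: 0.0, CH2: 0.0}
  SER: {formal_charge: 0, atoms: {CB: 0.0, OG: 0.0}}
  THR: {formal_charge: 0, atoms: {CB: 0.0, OG1: 0.0, CG2: 0.0}}
  ASN: {formal_charge: 0, atoms: {CB: 0.0, CG: 0.55, OD1: -0.55, ND2: 0.0}}
  GLN: {formal_charge: 0, atoms: {CB: 0.0, CG: 0.0, CD: 0.55, OE1: -0.55, NE2: 0.0}}
  ASP:
    titratable: true
    acid_or_base: acid
    model_pka: 4.0
    atoms: {CB: 0.0}
    variant_atoms: [CG, OD1, OD2]
    protonated: {CG: 0.20, OD1: -0.30, OD2: 0.10}
    deprotonated: {CG: 0.10, OD1: -0.55, OD2: -0.55}
  GLU:
    titratable: true
    acid_or_base: acid
    model_pka: 4.4
    atoms: {CB: 0.0, CG: 0.0}
    variant_atoms: [CD, OE1, OE2]
    protonated: {CD: 0.20, OE1: -0.30, OE2: 0.10}
    deprotonated: {CD: 0.10, OE1: -0.55, OE2: -0.55}
  TYR:
    titratable: true
    acid_or_base: acid
    model_pka: 9.6
    atoms: {CB: 0.0, CG: 0.0, CD1: 0.0, CD2: 0.0, CE1: 0.0, CE2: 0.0}
    variant_atoms: [CZ, OH]
    protonated: {CZ: 0.15, OH: -0.15}
    deprotonated: {CZ: -0.15, OH: -0.85}
  CYS:
    titratable: true
    acid_or_base: acid
    model_pka: 8.3
    atoms: {CB: 0.0}
    variant_atoms: [SG]
    protonated: {SG: 0.0}
    deprotonated: {SG: -1.0}
  LYS:
    titratable: true
    acid_or_base: base
    model_pka: 10.4
    atoms: {CB: 0.0, CG: 0.0, CD: 0.0, CE: 0.0}
    variant_atoms: [NZ]
    protonated: {NZ: 1.0}
    deprotonated: {NZ: 0.0}
  ARG:
    titratable: true
    acid_or_base: base
    model_pka: 12.0
    atoms: {CB: 0.0, CG: 0.0, CD: 0.0}
    variant_atoms: [NE, CZ, NH1, NH2]
    protonated: {NE: -0.10, CZ: 0.50, NH1: 0.30, NH2: 0.30}
    deprotonated: {NE: -0.30, CZ: 0.30, NH1: 0.0, NH2: 0.0}
  HIS:
    titratable: true
    acid_or_base: base
    model_pka: 6.3
    atoms: {CB: 0.0, CG: 0.0, CD2: 0.0, CE1: 0.0}
    variant_atoms: [ND1, NE2]
    protonated: {ND1: 0.50, NE2: 0.50}
    deprotonated: {ND1: -0.25, NE2: 0.25}
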