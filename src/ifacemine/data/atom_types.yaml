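# Physicochemical atom typing for the 20 standard amino acids.
#
# Long label names: ACP acceptor, ARM aromatic, DON donor, HPB hydrophobic,
# NEG negative, POS positive.  `backbone` applies to every residue and may be
# overridden per residue (proline's amide nitrogen carries no hydrogen and is
# therefore not a donor).  Atoms absent from the table receive no labels and
# never enter interface graphs.  The file can be replaced via configuration.
backbone:
  N: [DON]
  O: [ACP]
  OXT: [ACP, NEG]
  CA: [HPB]
residues:
  ALA:
    CB: [HPB]
  ARG:
    CB: [HPB]
    CG: [HPB]
    NE: [DON, POS]
    CZ: [POS]
    NH1: [DON, POS]
    NH2: [DON, POS]
  ASN:
    CB: [HPB]
    OD1: [ACP]
    ND2: [DON]
  ASP:
    CB: [HPB]
    OD1: [ACP, NEG]
    OD2: [ACP, NEG]
  CYS:
    CB: [HPB]
    SG: [ACP, DON]
  GLN:
    CB: [HPB]
    CG: [HPB]
    OE1: [ACP]
    NE2: [DON]
  GLU:
    CB: [HPB]
    CG: [HPB]
    OE1: [ACP, NEG]
    OE2: [ACP, NEG]
  GLY: {}
  HIS:
    CB: [HPB]
    CG: [ARM]
    ND1: [ARM, POS, DON, ACP]
    CD2: [ARM]
    CE1: [ARM]
    NE2: [ARM, POS, DON, ACP]
  ILE:
    CB: [HPB]
    CG1: [HPB]
    CG2: [HPB]
    CD1: [HPB]
  LEU:
    CB: [HPB]
    CG: [HPB]
    CD1: [HPB]
    CD2: [HPB]
  LYS:
    CB: [HPB]
    CG: [HPB]
    CD: [HPB]
    NZ: [DON, POS]
  MET:
    CB: [HPB]
    CG: [HPB]
    SD: [HPB]
    CE: [HPB]
  PHE:
    CB: [HPB]
    CG: [ARM]
    CD1: [ARM]
    CD2: [ARM]
    CE1: [ARM]
    CE2: [ARM]
    CZ: [ARM]
  PRO:
    N: []
    CB: [HPB]
    CG: [HPB]
    CD: [HPB]
  SER:
    OG: [ACP, DON]
  THR:
    OG1: [ACP, DON]
    CG2: [HPB]
  TRP:
    CB: [HPB]
    CG: [ARM]
    CD1: [ARM]
    CD2: [ARM]
    NE1: [ARM, DON]
    CE2: [ARM]
    CE3: [ARM]
    CZ2: [ARM]
    CZ3: [ARM]
    CH2: [ARM]
  TYR:
    CB: [HPB]
    CG: [ARM]
    CD1: [ARM]
    CD2: [ARM]
    CE1: [ARM]
    CE2: [ARM]
    CZ: [ARM]
    OH: [ACP, DON]
  VAL:
    CB: [HPB]
    CG1: [HPB]
    CG2: [HPB]
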