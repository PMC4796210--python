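# Simplified force-field typing table.
#
# vdw_classes: per-class Lennard-Jones parameters (rmin_half in Angstrom,
# epsilon in kcal/mol, combined with Lorentz-Berthelot rules).
# residues: (residue_name, atom_name) -> [vdw_class, partial_charge, hbond_role]
# The _backbone block applies to every standard amino acid; residue-specific
# entries override or extend it.  elements: fallback typing for atoms not
# covered by the residue table (neutral charge).

vdw_classes:
  carbon_sp3:          {rmin_half: 2.00, epsilon: 0.10}
  carbon_sp2_aromatic: {rmin_half: 1.95, epsilon: 0.12}
  polar_N:             {rmin_half: 1.85, epsilon: 0.17}
  polar_O:             {rmin_half: 1.70, epsilon: 0.21}
  sulfur:              {rmin_half: 2.00, epsilon: 0.25}
  hydrogen:            {rmin_half: 0.60, epsilon: 0.01}

_backbone:
  N:   [polar_N, -0.42, donor]
  CA:  [carbon_sp3, 0.03, none]
  C:   [carbon_sp2_aromatic, 0.60, none]
  O:   [polar_O, -0.57, acceptor]
  OXT: [polar_O, -0.57, acceptor]

residues:
  ALA:
    CB: [carbon_sp3, 0.0, none]
  ARG:
    CB: [carbon_sp3, 0.0, none]
    CG: [carbon_sp3, 0.0, none]
    CD: [carbon_sp3, 0.09, none]
    NE: [polar_N, -0.53, donor]
    CZ: [carbon_sp2_aromatic, 0.64, none]
    NH1: [polar_N, -0.63, donor]
    NH2: [polar_N, -0.63, donor]
  ASN:
    CB: [carbon_sp3, 0.0, none]
    CG: [carbon_sp2_aromatic, 0.55, none]
    OD1: [polar_O, -0.55, acceptor]
    ND2: [polar_N, -0.62, donor]
  ASP:
    CB: [carbon_sp3, 0.0, none]
    CG: [carbon_sp2_aromatic, 0.62, none]
    OD1: [polar_O, -0.71, acceptor]
    OD2: [polar_O, -0.71, acceptor]
  CYS:
    CB: [carbon_sp3, 0.0, none]
    SG: [sulfur, -0.23, donor]
  GLN:
    CB: [carbon_sp3, 0.0, none]
    CG: [carbon_sp3, 0.0, none]
    CD: [carbon_sp2_aromatic, 0.55, none]
    OE1: [polar_O, -0.55, acceptor]
    NE2: [polar_N, -0.62, donor]
  GLU:
    CB: [carbon_sp3, 0.0, none]
    CG: [carbon_sp3, 0.0, none]
    CD: [carbon_sp2_aromatic, 0.62, none]
    OE1: [polar_O, -0.71, acceptor]
    OE2: [polar_O, -0.71, acceptor]
  GLY: {}
  HIS:
    CB: [carbon_sp3, 0.0, none]
    CG: [carbon_sp2_aromatic, 0.0, none]
    ND1: [polar_N, -0.38, acceptor]
    CD2: [carbon_sp2_aromatic, 0.0, none]
    CE1: [carbon_sp2_aromatic, 0.2, none]
    NE2: [polar_N, -0.28, donor]
  ILE:
    CB: [carbon_sp3, 0.0, none]
    CG1: [carbon_sp3, 0.0, none]
    CG2: [carbon_sp3, 0.0, none]
    CD1: [carbon_sp3, 0.0, none]
  LEU:
    CB: [carbon_sp3, 0.0, none]
    CG: [carbon_sp3, 0.0, none]
    CD1: [carbon_sp3, 0.0, none]
    CD2: [carbon_sp3, 0.0, none]
  LYS:
    CB: [carbon_sp3, 0.0, none]
    CG: [carbon_sp3, 0.0, none]
    CD: [carbon_sp3, 0.0, none]
    CE: [carbon_sp3, 0.2, none]
    NZ: [polar_N, 0.3, donor]
  MET:
    CB: [carbon_sp3, 0.0, none]
    CG: [carbon_sp3, 0.0, none]
    SD: [sulfur, -0.27, acceptor]
    CE: [carbon_sp3, 0.0, none]
  PHE:
    CB: [carbon_sp3, 0.0, none]
    CG: [carbon_sp2_aromatic, 0.0, none]
    CD1: [carbon_sp2_aromatic, 0.0, none]
    CD2: [carbon_sp2_aromatic, 0.0, none]
    CE1: [carbon_sp2_aromatic, 0.0, none]
    CE2: [carbon_sp2_aromatic, 0.0, none]
    CZ: [carbon_sp2_aromatic, 0.0, none]
  PRO:
    N: [polar_N, -0.3, none]
    CB: [carbon_sp3, 0.0, none]
    CG: [carbon_sp3, 0.0, none]
    CD: [carbon_sp3, 0.0, none]
  SER:
    CB: [carbon_sp3, 0.2, none]
    OG: [polar_O, -0.66, both]
  THR:
    CB: [carbon_sp3, 0.27, none]
    OG1: [polar_O, -0.66, both]
    CG2: [carbon_sp3, 0.0, none]
  TRP:
    CB: [carbon_sp3, 0.0, none]
    CG: [carbon_sp2_aromatic, 0.0, none]
    CD1: [carbon_sp2_aromatic, 0.0, none]
    CD2: [carbon_sp2_aromatic, 0.0, none]
    NE1: [polar_N, -0.34, donor]
    CE2: [carbon_sp2_aromatic, 0.0, none]
    CE3: [carbon_sp2_aromatic, 0.0, none]
    CZ2: [carbon_sp2_aromatic, 0.0, none]
    CZ3: [carbon_sp2_aromatic, 0.0, none]
    CH2: [carbon_sp2_aromatic, 0.0, none]
  TYR:
    CB: [carbon_sp3, 0.0, none]
    CG: [carbon_sp2_aromatic, 0.0, none]
    CD1: [carbon_sp2_aromatic, 0.0, none]
    CD2: [carbon_sp2_aromatic, 0.0, none]
    CE1: [carbon_sp2_aromatic, 0.0, none]
    CE2: [carbon_sp2_aromatic, 0.0, none]
    CZ: [carbon_sp2_aromatic, 0.12, none]
    OH: [polar_O, -0.56, both]
  HOH:
    O:  [polar_O, -0.834, both]
    OW: [polar_O, -0.834, both]
    H1: [hydrogen, 0.417, none]
    H2: [hydrogen, 0.417, none]
  # Synthetic fixture residues: cavity wall carbons and the rigid toy ligand.
  SHL:
    CA: [carbon_sp3, 0.0, none]
  LIG:
    O1: [polar_O, -0.55, both]
    N1: [polar_N, -0.50, both]
    CM: [carbon_sp3, 0.0, none]

elements:
  C: [carbon_sp3, 0.0, none]
  N: [polar_N, 0.0, both]
  O: [polar_O, 0.0, both]
  S: [sulfur, 0.0, acceptor]
  H: [hydrogen, 0.0, none]
  P: [sulfur, 0.0, none]
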