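# Hydrogen-bond atom classes used by the similarity metric and the H-bond
# analyses. Four classes: donor, acceptor, both, nonpolar.
#
# Lookup order for an atom (residue R, name A):
#   1. residues[R][A] if present
#   2. backbone[A] for standard amino acids (and listed modified residues)
#   3. elements[element] fallback
# Unknown names either warn-and-default to the element rule or raise,
# depending on the `strict` flag of assign_atom_classes.
#
# This file is package data and deliberately editable: crystallographic and
# NMR files vary in naming, and protonation conventions differ between
# force fields.

backbone:
  N: donor
  H: donor
  HN: donor
  O: acceptor
  OXT: acceptor
  OT1: acceptor
  OT2: acceptor

elements:
  N: donor
  O: acceptor
  S: nonpolar
  P: nonpolar
  C: nonpolar
  H: nonpolar

residues:
  PRO: {N: nonpolar}
  SER: {OG: both, HG: donor, HG1: donor}
  THR: {OG1: both, HG1: donor}
  TYR: {OH: both, HH: donor}
  CYS: {SG: nonpolar}
  MET: {SD: nonpolar}
  ASN: {OD1: acceptor, ND2: donor, HD21: donor, HD22: donor}
  GLN: {OE1: acceptor, NE2: donor, HE21: donor, HE22: donor}
  ASP: {OD1: acceptor, OD2: acceptor}
  GLU: {OE1: acceptor, OE2: acceptor}
  LYS: {NZ: donor, HZ1: donor, HZ2: donor, HZ3: donor}
  ARG: {NE: donor, HE: donor, NH1: donor, NH2: donor,
        HH11: donor, HH12: donor, HH21: donor, HH22: donor}
  HIS: {ND1: both, NE2: both, HD1: donor, HE2: donor}
  TRP: {NE1: donor, HE1: donor}
  # phosphoserine: bridging ester oxygen accepts; phosphate oxygens accept
  SEP: {OG: acceptor, P: nonpolar, O1P: acceptor, O2P: acceptor, O3P: acceptor,
        OT: acceptor}
  # acetyl cap CH3-CO-
  ACE: {C: nonpolar, O: acceptor, CH3: nonpolar, CA: nonpolar}
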