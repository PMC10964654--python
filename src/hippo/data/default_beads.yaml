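# Default atom -> bead typing table.
#
# Protein: every residue contributes 2 backbone beads (shared types 1-2)
# plus 0-2 side-chain beads with residue-specific types (3-31), 31 types
# in total.  RNA: every nucleotide contributes 1 phosphate bead (type 1),
# 2 sugar beads (types 2-3) and 3-4 base beads (types 4-17), 17 types in
# total.  Bead positions are the unweighted geometric centre of the heavy
# atoms listed for each group.
protein:
  backbone:
    - {index: 1, label: bb-amine, atoms: [N, CA]}
    - {index: 2, label: bb-carbonyl, atoms: [C, O]}
  side_chains:
    GLY: []
    ALA:
      - {index: 3, label: ala-methyl, atoms: [CB]}
    SER:
      - {index: 4, label: ser-hydroxyl, atoms: [CB, OG]}
    CYS:
      - {index: 5, label: cys-thiol, atoms: [CB, SG]}
    THR:
      - {index: 6, label: thr-hydroxyl, atoms: [CB, OG1, CG2]}
    VAL:
      - {index: 7, label: val-branch, atoms: [CB, CG1, CG2]}
    PRO:
      - {index: 8, label: pro-ring, atoms: [CB, CG, CD]}
    ASP:
      - {index: 9, label: asp-carboxyl, atoms: [CB, CG, OD1, OD2]}
    ASN:
      - {index: 10, label: asn-amide, atoms: [CB, CG, OD1, ND2]}
    LEU:
      - {index: 11, label: leu-branch, atoms: [CB, CG, CD1, CD2]}
    ILE:
      - {index: 12, label: ile-branch, atoms: [CB, CG1, CG2]}
      - {index: 13, label: ile-tip, atoms: [CD1]}
    MET:
      - {index: 14, label: met-stem, atoms: [CB, CG]}
      - {index: 15, label: met-thioether, atoms: [SD, CE]}
    GLU:
      - {index: 16, label: glu-stem, atoms: [CB, CG]}
      - {index: 17, label: glu-carboxyl, atoms: [CD, OE1, OE2]}
    GLN:
      - {index: 18, label: gln-stem, atoms: [CB, CG]}
      - {index: 19, label: gln-amide, atoms: [CD, OE1, NE2]}
    LYS:
      - {index: 20, label: lys-stem, atoms: [CB, CG, CD]}
      - {index: 21, label: lys-ammonium, atoms: [CE, NZ]}
    ARG:
      - {index: 22, label: arg-stem, atoms: [CB, CG, CD]}
      - {index: 23, label: arg-guanidinium, atoms: [NE, CZ, NH1, NH2]}
    HIS:
      - {index: 24, label: his-stem, atoms: [CB, CG]}
      - {index: 25, label: his-imidazole, atoms: [ND1, CD2, CE1, NE2]}
    PHE:
      - {index: 26, label: phe-ring-a, atoms: [CB, CG, CD1, CD2]}
      - {index: 27, label: phe-ring-b, atoms: [CE1, CE2, CZ]}
    TYR:
      - {index: 28, label: tyr-ring-a, atoms: [CB, CG, CD1, CD2]}
      - {index: 29, label: tyr-ring-b, atoms: [CE1, CE2, CZ, OH]}
    TRP:
      - {index: 30, label: trp-pyrrole, atoms: [CB, CG, CD1, NE1]}
      - {index: 31, label: trp-benzene, atoms: [CD2, CE2, CE3, CZ2, CZ3, CH2]}
rna:
  backbone:
    - {index: 1, label: phosphate, atoms: [P, OP1, OP2]}
    - {index: 2, label: sugar-1, atoms: ["C5'", "C4'", "O4'"]}
    - {index: 3, label: sugar-2, atoms: ["C3'", "C2'", "C1'", "O2'", "O3'"]}
  bases:
    A:
      - {index: 4, label: ade-imidazole, atoms: [N9, C8, N7]}
      - {index: 5, label: ade-junction, atoms: [C4, C5]}
      - {index: 6, label: ade-amine, atoms: [C6, N6, N1]}
      - {index: 7, label: ade-edge, atoms: [C2, N3]}
    G:
      - {index: 8, label: gua-imidazole, atoms: [N9, C8, N7]}
      - {index: 9, label: gua-junction, atoms: [C4, C5]}
      - {index: 10, label: gua-keto, atoms: [C6, O6, N1]}
      - {index: 11, label: gua-amine, atoms: [C2, N2, N3]}
    C:
      - {index: 12, label: cyt-keto, atoms: [N1, C2, O2]}
      - {index: 13, label: cyt-amine, atoms: [N3, C4, N4]}
      - {index: 14, label: cyt-edge, atoms: [C5, C6]}
    U:
      - {index: 15, label: ura-keto, atoms: [N1, C2, O2]}
      - {index: 16, label: ura-imide, atoms: [N3, C4, O4]}
      - {index: 17, label: ura-edge, atoms: [C5, C6]}
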