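{
  "_comment": "Heavy-atom hydrogen-bond donor/acceptor typing for standard amino acids. Backbone: N donates, O/OXT accepts (all residues). Side chains listed per residue. His and hydroxyl oxygens are both donor and acceptor (protonation unknown in an X-ray structure without hydrogens).",
  "backbone_donors": ["N"],
  "backbone_acceptors": ["O", "OXT"],
  "sidechain_donors": {
    "ARG": ["NE", "NH1", "NH2"],
    "LYS": ["NZ"],
    "HIS": ["ND1", "NE2"],
    "ASN": ["ND2"],
    "GLN": ["NE2"],
    "SER": ["OG"],
    "THR": ["OG1"],
    "TYR": ["OH"],
    "TRP": ["NE1"]
  },
  "sidechain_acceptors": {
    "ASP": ["OD1", "OD2"],
    "GLU": ["OE1", "OE2"],
    "ASN": ["OD1"],
    "GLN": ["OE1"],
    "SER": ["OG"],
    "THR": ["OG1"],
    "TYR": ["OH"],
    "HIS": ["ND1", "NE2"],
    "MET": ["SD"]
  }
}
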