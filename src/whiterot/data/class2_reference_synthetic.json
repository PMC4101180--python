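{
 "name": "class2_reference_synthetic",
 "comment": "Synthetic class II peroxidase reference template. Not a real protein: a constructed stand-in with the canonical VP-type catalytic features planted at mature-protein-numbering positions (Mn-oxidation site Glu36/Glu40/Asp175, distal Arg43/His47, catalytic Trp164, proximal His169, eight cysteines). Positions are 1-based on the template.",
 "sequence": "DECTYVSEHMNIKQCEDNTHNHLSDGVVDQDMPCLEHVYEFTRYEFHDPNETEGLMHATQENGAHGPDMSQKLFIVNHVEYVHFMILVYEMDMGMITTAPLADDDKSDVGRMLNLDDIYCGNQETAVQLYFDFTLNGNGGAPHKTYTDPHLDMVDQVNMEHVIWTYMKHPPLHKDGSYRMIFFQGSDTNHFAFDFTLNDYDLVMAKSKYVKEIDGLFLMTNDELFYANDRGHELKELKNMEYCKSKTTKYTRCQGVDLMTDLVMHHRMIVTDASPSSTRQAKLVCHQKVKSNQNVIEQSAETKPRRSLGERPPHCYGFVSLHIKYTPAQRE",
 "tail_boundary": 331,
 "features": {
  "mn_site": {
   "36": "E",
   "40": "E",
   "175": "D"
  },
  "distal_arg": {
   "43": "R"
  },
  "distal_his": {
   "47": "H"
  },
  "catalytic_trp": {
   "164": "W"
  },
  "proximal_his": {
   "169": "H"
  },
  "cysteines": {
   "3": "C",
   "15": "C",
   "34": "C",
   "120": "C",
   "243": "C",
   "253": "C",
   "285": "C",
   "315": "C"
  },
  "calcium_ligands": {
   "48": "D",
   "66": "G",
   "68": "D",
   "70": "S",
   "177": "S",
   "194": "D",
   "196": "T",
   "199": "D"
  }
 }
}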