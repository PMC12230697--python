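# Nucleotide building-block library for oligonucleotide SMILES assembly.
#
# Sugars are SMILES templates written 5'->3': the first atom is C5' (it
# bonds to whatever precedes it in the assembled string: the 5'-OH
# terminus or a phosphate linkage) and the last atom is O3' (it bonds to
# the next linkage's phosphorus, or keeps an implicit H as the 3'-OH
# terminus). `{b}` marks where the base substituent attaches to C1'.
# Ring-closure digits 1-2 are reserved for sugars, 8-9 for bases, so a
# template and its base never collide and templates can repeat along a
# chain.
#
# Bases are SMILES substituents whose first atom is the glycosidic
# nitrogen (N1 of pyrimidines, N9 of purines).
#
# Linkages bridge a 3'-O to the next residue's 5'-C. Phosphates are the
# neutral protonated forms with no stereo descriptor on phosphorus.
#
# New 2'-chemistries (e.g. 2'-OMe, 2'-F) can be registered by adding a
# sugar template here; no code change is needed.

sugars:
  DNA:
    template: "C[C@H]1O[C@@H]({b})C[C@@H]1O"
    description: "2'-deoxy-beta-D-ribofuranose"
  LNA:
    template: "CC12O[C@@H]({b})[C@H](OC1)[C@H]2O"
    description: "locked nucleic acid: 2'-O,4'-C-methylene-bridged ribose"
  MOE:
    template: "C[C@H]1O[C@@H]({b})[C@H](OCCOC)[C@@H]1O"
    description: "2'-O-methoxyethyl ribose"

bases:
  T:
    smiles: "N8C=C(C)C(=O)NC8=O"
    description: "thymine (N1 attachment)"
  U:
    smiles: "N8C=CC(=O)NC8=O"
    description: "uracil (N1 attachment)"
  C:
    smiles: "N8C=CC(N)=NC8=O"
    description: "cytosine (N1 attachment)"
  5MeC:
    smiles: "N8C=C(C)C(N)=NC8=O"
    description: "5-methylcytosine (N1 attachment)"
  A:
    smiles: "n8cnc9c(N)ncnc89"
    description: "adenine (N9 attachment)"
  G:
    smiles: "n8cnc9c(=O)[nH]c(N)nc89"
    description: "guanine (N9 attachment)"

linkages:
  PO:
    smiles: "P(=O)(O)O"
    description: "phosphodiester, neutral protonated"
  PS:
    smiles: "P(=S)(O)O"
    description: "phosphorothioate, neutral protonated, Rp/Sp unresolved"

# Which base ring each (sugar, sequence letter) combination carries.
# MOE pyrimidines follow MOE-chemistry convention: T is built as the
# uridine analogue (the thymine 5-methyl is the uracil ring + the MOE
# naming), C as 5-methylcytosine. LNA and DNA keep the DNA base identity.
base_for_sugar:
  DNA: {A: A, T: T, C: C, G: G}
  LNA: {A: A, T: T, C: C, G: G}
  MOE: {A: A, T: U, C: 5MeC, G: G}
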