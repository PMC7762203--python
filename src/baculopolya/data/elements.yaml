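# Default cis-element definitions (IUPAC, T/U interchangeable).
# "G-RICH" is a sentinel: Aux-DSE hits are windows of length 6 with >= 4 G.
elements:
  - {class: USE, motifs: [TTTT], description: "U-rich upstream sequence element"}
  - {class: UGUA, motifs: [TGTA], description: "CFIm recognition motif"}
  - {class: PAS, motifs: [AATAAA, ATTAAA], description: "polyadenylation signal"}
  - {class: CS, motifs: [CA], description: "cleavage just 3' of a CA dinucleotide"}
  - {class: DSE, motifs: [TTTTT, GTTGT], description: "CstF-bound downstream element"}
  - {class: AuxDSE, motifs: [G-RICH], description: "G-rich auxiliary element"}
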