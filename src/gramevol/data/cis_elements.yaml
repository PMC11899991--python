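# Consensus catalog of plant cis-acting regulatory elements, PlantCARE-style
# names with IUPAC degenerate patterns. The patterns are widely used consensus
# sequences; scanning is exact degenerate matching on both strands.
motifs:
  - {name: ABRE,            iupac: ACGTG,      category: phytohormone}   # abscisic acid responsiveness
  - {name: CGTCA-motif,     iupac: CGTCA,      category: phytohormone}   # MeJA responsiveness
  - {name: TGACG-motif,     iupac: TGACG,      category: phytohormone}   # MeJA responsiveness
  - {name: P-box,           iupac: CCTTTTG,    category: phytohormone}   # gibberellin responsiveness
  - {name: GARE-motif,      iupac: TCTGTTG,    category: phytohormone}   # gibberellin responsiveness
  - {name: TCA-element,     iupac: CCATCTTTTT, category: phytohormone}   # salicylic acid responsiveness
  - {name: TGA-element,     iupac: AACGAC,     category: phytohormone}   # auxin responsiveness
  - {name: AuxRR-core,      iupac: GGTCCAT,    category: phytohormone}   # auxin responsiveness
  - {name: G-box,           iupac: CACGTG,     category: light}
  - {name: TCT-motif,       iupac: TCTTAC,     category: light}
  - {name: GT1-motif,       iupac: GGTTAA,     category: light}
  - {name: Box-4,           iupac: ATTAAT,     category: light}
  - {name: ARE,             iupac: AAACCA,     category: stress}         # anaerobic induction
  - {name: MBS,             iupac: CAACTG,     category: stress}         # MYB binding site, drought
  - {name: LTR,             iupac: CCGAAA,     category: stress}         # low-temperature responsiveness
  - {name: TC-rich repeats, iupac: ATTTTCTTCA, category: stress}         # defense and stress
  - {name: WUN-motif,       iupac: AAATTTCCT,  category: stress}         # wound responsiveness
  - {name: CAT-box,         iupac: GCCACT,     category: development}    # meristem expression
  - {name: NON-box,         iupac: AGATTA,     category: development}    # meristem-specific activation
  - {name: RY-element,      iupac: CATGCATG,   category: development}    # seed-specific regulation
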