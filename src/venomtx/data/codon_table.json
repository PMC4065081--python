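{
  "version": "human-most-frequent-1",
  "comment": "One fixed codon per amino acid (most-used human codon) for deterministic reverse translation of template peptides; '*' is the stop codon used to terminate synthetic CDSs.",
  "codons": {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "AGA",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
    "*": "TGA"
  }
}
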