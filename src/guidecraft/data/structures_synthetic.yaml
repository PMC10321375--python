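# Special-structure templates and the default sgRNA scaffold.
# The hairpin and GOLD insert sequences below are SYNTHETIC PLACEHOLDERS
# (self-complementary stem-loops of the right general shape); replace them
# with lab-validated sequences from the primary literature before use.
default_scaffold: GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC
structures:
  identity:
    insert_seq: ""
    insert_position: three_prime
  hairpin:
    insert_seq: GGCGCGAAAGCGCC
    insert_position: five_prime
  GOLD:
    insert_seq: GCAGCCGAAAGGCTGC
    insert_position: three_prime
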