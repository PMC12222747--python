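"""Shared constants for HIC WD40 repeat analysis.

A single WD40 repeat unit in the HNWD sensor domain is 126 bp (42 aa).
Seven codon positions within the repeat are hypervariable (under
diversifying selection) and define a repeat variant; the remaining 35
positions are highly conserved within a gene.
"""

# Second HIC repeat of the het-e E2 allele, used throughout as the
# canonical het-e repeat consensus.
HET_E_CONSENSUS_AA = "TGTQTLEGHGGSVWSVAFSPDGQRVASGSDDKTIKIWDAASG"

REPEAT_LENGTH_AA = 42
REPEAT_PERIOD_NT = 126

# 1-based hypervariable positions within the 42-aa repeat.
HYPERVARIABLE_POSITIONS = (10, 11, 12, 14, 30, 32, 39)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

STOP_CODONS = ("TAA", "TAG", "TGA")
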