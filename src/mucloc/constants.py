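"""Shared lookup tables: IUPAC codes, codon usage, hydropathy, built-in assay reagents."""

# IUPAC nucleotide codes -> the set of concrete bases each code stands for.
# Used for degenerate primer / restriction-site matching: a template base
# matches a query code iff the base is a member of the code's set. Note that
# a template 'N' is a member of no set, so an assembly gap never satisfies a
# degenerate query.
IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# One fixed codon per amino acid (the most-used human codon), so that
# back-translating a protein repeat unit yields nucleotide-level perfect
# tandem repeats deterministically.
PREFERRED_CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGC",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
    "*": "TAA",
}

# Kyte-Doolittle hydropathy scale (kcal-free index units per residue).
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

# The 17-residue consensus repeat unit of the intestinal membrane-mucin
# PTS domain (15 of 17 residues are P/T/S).
MUC3_REPEAT_UNIT = "ITTTETTSHSTPSFTSS"

# Gene-specific RT-qPCR primer pairs discriminating the two near-identical
# MUC3 paralogs (exon 3 forward, exon 8 reverse; 5'->3').
MUC3A_FWD = "TGGGGGTCAGTGGGATGGCCTCAAA"
MUC3A_REV = "CACGTGGGACCGCTCGTCTCC"
MUC3B_FWD = "CGGGGGCCAGTGGGATGGCCTCAAG"
MUC3B_REV = "CACGCGGGACCGCTCGTCTCT"

# SYNTHETIC SEA-domain-like reference segment (96 aa). This is NOT a real
# SEA domain sequence: it is a fixed pseudo-sequence with SEA-like residue
# composition, planted by the synthetic-data generator into C-terminal
# regions and used as the default detection reference so that planted-truth
# round trips are exact.
SEA_REFERENCE_SYNTHETIC = (
    "LVDVRLSFNRALEDPSSEEYKALSQKVTDMLDEIYKGVPGFLRVNVTGFRQGSVVADYE"
    "VILEAPLSSEQVNSVLRQALNNSSNLGNLTVDTSSI"
)
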