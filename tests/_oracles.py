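"""Independent oracles frozen for the test suite.

These deliberately avoid the code paths they check: the genetic code is a
literal table (not Biopython's), and the genotype-enumeration selection
oracle is written from genotype frequencies rather than marginal fitnesses.
"""

# Standard genetic code, frozen as a literal (stop = '*').
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def degeneracy_oracle(codon: str, pos: int) -> str:
    """Brute-force fold class of a codon position from the literal code table."""
    aa = GENETIC_CODE[codon]
    n_same = sum(
        GENETIC_CODE[codon[:pos] + b + codon[pos + 1 :]] == aa for b in "ACGT"
    )
    return {1: "0", 2: "2", 4: "4"}.get(n_same, "other")


def selection_oracle(q: float, s: float, h: float) -> float:
    """Next-generation derived frequency via explicit genotype enumeration."""
    p = 1.0 - q
    f_hom_der = q * q * (1.0 - s)
    f_het = 2.0 * p * q * (1.0 - h * s)
    f_hom_anc = p * p
    wbar = f_hom_der + f_het + f_hom_anc
    return (f_hom_der + 0.5 * f_het) / wbar
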