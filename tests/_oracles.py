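"""Independent oracles used by the test suite.

These deliberately re-derive results through a different route than the
package: a quadratic three-matrix affine-gap Smith-Waterman for alignment
scores, and a hand-written codon table for CDS translation.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def sw_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Optimal local alignment score, affine gaps (gap of length L costs
    gap_open + L * gap_extend).  O(len(a)*len(b)) dynamic programme."""
    n, m = len(a), len(b)
    neg = float("-inf")
    first = gap_open + gap_extend
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            s = float(_B62[a[i - 1], b[j - 1]])
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


# standard genetic code (the bacterial table differs only in start codons,
# which do not affect internal translation)
_CODON_TABLE = {
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
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def translate_span(contig_seq: str, start: int, end: int, strand: str) -> str:
    """Per-codon translation of a 1-based inclusive span (oracle)."""
    nt = contig_seq[start - 1 : end]
    if strand == "-":
        nt = "".join(_COMP[c] for c in reversed(nt))
    aa = "".join(
        _CODON_TABLE.get(nt[i : i + 3], "X") for i in range(0, len(nt) - 2, 3)
    )
    return aa[:-1] if aa.endswith("*") else aa
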