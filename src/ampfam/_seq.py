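"""Small sequence helpers shared across the package.

Coordinates are 0-based, half-open everywhere; minus-strand intervals are
stored on the forward coordinate system.
"""

from __future__ import annotations

from Bio.Seq import Seq

DNA = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Codon used when back-translating each amino acid (one fixed codon per
#: residue keeps synthetic ancestors deterministic).
PREFERRED_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCA",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
    "*": "TAA",
}


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_cds(cds: str) -> str:
    """Translate a CDS codon by codon; internal STOPs become '*', codons
    containing non-ACGT characters become 'X'. No length-multiple check is
    enforced: a trailing partial codon is dropped."""
    pep = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3].upper()
        if any(b not in DNA for b in codon):
            pep.append("X")
        else:
            pep.append(str(Seq(codon).translate()))
    return "".join(pep)


def back_translate(peptide: str) -> str:
    """Deterministic back-translation using one fixed codon per residue."""
    try:
        return "".join(PREFERRED_CODON[aa] for aa in peptide)
    except KeyError as exc:  # pragma: no cover - guarded by callers
        raise ValueError(f"cannot back-translate residue {exc}") from exc


def is_valid_dna(seq: str) -> bool:
    return all(b in "ACGTN" for b in seq.upper())


def has_internal_stop(cds: str) -> bool:
    """True if any codon before the final one is a STOP codon."""
    n_codons = len(cds) // 3
    for i in range(n_codons - 1):
        if cds[3 * i : 3 * i + 3].upper() in STOP_CODONS:
            return True
    return False
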