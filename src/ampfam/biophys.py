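"""Mature-peptide delimitation and charge biophysics.

Net charge follows the Henderson-Hasselbalch form

    Q(pH) = sum_basic 1/(1+10^(pH-pKa)) - sum_acidic 1/(1+10^(pKa-pH))

with basic groups {N-terminus, K, R, H} and acidic {C-terminus, D, E, C, Y}.
Q is strictly decreasing in pH, so the isoelectric point (Q(pI) = 0) is
found by bisection on [0, 14]. Cysteines are treated as free thiols; 'X'
residues contribute no charge and 110 Da to the molecular weight.

Two pKa tables ship: IPC_protein (default) and IPC_peptide.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import GAP
from .catalog import _protein_global_aligner

CYTOPLASMIC_PH = 7.4
SLIDING_WINDOW = 15


@dataclass(frozen=True)
class PKaTable:
    n_term: float
    c_term: float
    C: float
    D: float
    E: float
    H: float
    K: float
    R: float
    Y: float
    source: str = "custom"

    def __post_init__(self):
        for name in ("n_term", "c_term", "C", "D", "E", "H", "K", "R", "Y"):
            v = getattr(self, name)
            if not 0.0 < v < 14.0:
                raise ValueError(f"pKa {name}={v} outside (0,14)")


IPC_PROTEIN = PKaTable(n_term=9.094, c_term=2.869, C=7.555, D=3.872, E=4.412,
                       H=5.637, K=9.052, R=11.84, Y=10.85, source="IPC_protein")
IPC_PEPTIDE = PKaTable(n_term=9.564, c_term=2.383, C=8.297, D=3.887, E=4.317,
                       H=6.018, K=10.517, R=12.503, Y=10.071, source="IPC_peptide")

#: Average residue masses (Da); full-peptide MW adds one water.
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
    "X": 110.0,
}
_WATER = 18.0153


def net_charge(peptide: str, pH: float, pka: PKaTable = IPC_PROTEIN,
               free_termini: bool = True) -> float:
    """Net charge (elementary charges) at the given pH."""
    if not peptide:
        raise ValueError("empty peptide")
    q = 0.0
    if free_termini:
        q += 1.0 / (1.0 + 10.0 ** (pH - pka.n_term))
        q -= 1.0 / (1.0 + 10.0 ** (pka.c_term - pH))
    for aa in peptide:
        if aa in "KRH":
            q += 1.0 / (1.0 + 10.0 ** (pH - getattr(pka, aa)))
        elif aa in "DECY":
            q -= 1.0 / (1.0 + 10.0 ** (getattr(pka, aa) - pH))
    return q


def isoelectric_point(peptide: str, pka: PKaTable = IPC_PROTEIN,
                      tol: float = 1e-3, free_termini: bool = True) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14]."""
    has_basic = free_termini or any(aa in "KRH" for aa in peptide)
    has_acidic = free_termini or any(aa in "DECY" for aa in peptide)
    if not (has_basic and has_acidic):
        raise ValueError("pI undefined: need an ionizable group of each sign")
    lo, hi = 0.0, 14.0
    # Q is strictly decreasing, so bisect on its sign; iterating to a narrow
    # bracket (1e-6 pH) also drives |Q(pI)| below tol near the root, which a
    # bare |Q| < tol stop would not guarantee where the titration curve is flat.
    while hi - lo > 1e-6:
        mid = (lo + hi) / 2
        if net_charge(peptide, mid, pka, free_termini) > 0:
            lo = mid
        else:
            hi = mid
    pi = (lo + hi) / 2
    if abs(net_charge(peptide, pi, pka, free_termini)) >= tol:  # pragma: no cover
        raise ArithmeticError("bisection failed to reach |Q| < tol")
    return pi


def molecular_weight(peptide: str) -> float:
    """Average molecular weight in Da ('X' counted at 110 Da)."""
    if not peptide:
        raise ValueError("empty peptide")
    return sum(_RESIDUE_MASS.get(aa, 110.0) for aa in peptide) + _WATER


def sliding_pi(peptide: str, window: int = SLIDING_WINDOW,
               pka: PKaTable = IPC_PROTEIN, free_termini: bool = True) -> list[float]:
    """pI of every length-`window` subsequence (free termini by default);
    empty when the peptide is shorter than the window."""
    if window < 2:
        raise ValueError("window must be >= 2")
    return [isoelectric_point(peptide[i:i + window], pka, free_termini=free_termini)
            for i in range(len(peptide) - window + 1)]


def mature_boundaries(precursor: str, reference_mature: str) -> tuple[int, int]:
    """Mature-peptide interval on the precursor (0-based half-open).

    The precursor is globally aligned (end gaps free) to the reference
    mature peptide; the start maps to the reference's first residue and the
    end to its conserved C-terminal Arg column, taken from the reference
    column even when the aligned residue is not Arg.
    """
    aligner = _protein_global_aligner()
    aln = aligner.align(precursor, reference_mature)[0]
    row_pre, row_ref = str(aln[0]), str(aln[1])
    pre_i = 0
    start = end = None
    ref_i = 0
    for col in range(len(row_ref)):
        if row_ref[col] != GAP:
            if ref_i == 0:
                start = pre_i
            if ref_i == len(reference_mature) - 1:
                end = pre_i + (1 if row_pre[col] != GAP else 0)
            ref_i += 1
        if row_pre[col] != GAP:
            pre_i += 1
    if start is None or end is None:  # pragma: no cover
        raise ValueError("reference does not align to precursor")
    return start, end


def mature_peptide(precursor: str, reference_mature: str) -> str:
    s, e = mature_boundaries(precursor, reference_mature)
    return precursor[s:e]


def profile_peptide(peptide: str, pka: PKaTable = IPC_PROTEIN) -> dict:
    """pI, charge at cytoplasmic pH, MW and the 15-residue sliding series."""
    return {
        "pI": isoelectric_point(peptide, pka),
        "charge_at_7_4": net_charge(peptide, CYTOPLASMIC_PH, pka),
        "mw": molecular_weight(peptide),
        "sliding_pi": sliding_pi(peptide, pka=pka),
    }
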