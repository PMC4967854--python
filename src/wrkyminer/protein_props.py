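"""Molecular weight and isoelectric point from protein sequence."""

from __future__ import annotations

from dataclasses import dataclass

WATER_DA = 18.0153

#: average residue masses (Da) — monomer mass minus one water
AVG_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_MEAN_RESIDUE_MASS = sum(AVG_RESIDUE_MASS.values()) / len(AVG_RESIDUE_MASS)

#: default pKa compilation: sidechains plus termini
DEFAULT_PKA = {
    "n_term": 8.6, "c_term": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
}
_BASIC = ("n_term", "H", "K", "R")
_ACIDIC = ("c_term", "C", "D", "E", "Y")


@dataclass(frozen=True)
class ProteinProperties:
    protein_id: str
    length: int
    mw_da: float
    pi: float


def molecular_weight(seq: str, allow_x: bool = False) -> float:
    """Average molecular mass in Daltons: residue masses plus one water."""
    if not seq:
        raise ValueError("empty sequence")
    total = WATER_DA
    for res in seq:
        if res in AVG_RESIDUE_MASS:
            total += AVG_RESIDUE_MASS[res]
        elif res == "X" and allow_x:
            total += _MEAN_RESIDUE_MASS
        else:
            raise ValueError(f"unknown residue {res!r}")
    return total


def net_charge(seq: str, ph: float, pka: dict[str, float] | None = None) -> float:
    """Henderson–Hasselbalch net charge at the given pH."""
    pka = pka or DEFAULT_PKA
    counts = {g: seq.count(g) for g in "CDEHKRY"}
    counts["n_term"] = counts["c_term"] = 1
    q = 0.0
    for g in _BASIC:
        if g in pka and counts.get(g, 0):
            q += counts[g] / (1.0 + 10.0 ** (ph - pka[g]))
    for g in _ACIDIC:
        if g in pka and counts.get(g, 0):
            q -= counts[g] / (1.0 + 10.0 ** (pka[g] - ph))
    return q


def isoelectric_point(seq: str, pka: dict[str, float] | None = None,
                      tol: float = 1e-6) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    The charge function is strictly decreasing in pH, so the root is unique.
    """
    if not seq:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def protein_properties(protein_id: str, seq: str,
                       pka: dict[str, float] | None = None,
                       allow_x: bool = False) -> ProteinProperties:
    return ProteinProperties(
        protein_id=protein_id, length=len(seq),
        mw_da=molecular_weight(seq, allow_x=allow_x),
        pi=isoelectric_point(seq, pka),
    )
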