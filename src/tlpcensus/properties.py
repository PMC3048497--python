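"""Physicochemical descriptors: average molecular weight and isoelectric point.

Molecular weight uses average (not monoisotopic) residue masses plus one
water, matching kDa-scale reporting.  The isoelectric point is the unique
root of the Henderson-Hasselbalch net-charge function, found by bisection;
the default pKa set is the EMBOSS table, packaged as a swappable mapping
since published pI values depend on the tool's pKa choices.
"""

from __future__ import annotations

from dataclasses import dataclass

WATER_MASS = 18.0153

#: average residue masses (monomer minus water), Da
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

#: EMBOSS pKa values; "nterm"/"cterm" are the free termini
PKA_EMBOSS = {
    "nterm": 8.6, "cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "Y": 10.1,  # acidic side chains
    "H": 6.5, "K": 10.8, "R": 12.5,  # basic side chains
}

ACIDIC = ("D", "E", "C", "Y")
BASIC = ("H", "K", "R")


@dataclass(frozen=True)
class PhysProps:
    protein_id: str
    mw_kda: float
    pi: float
    domain_coverage: float | None = None


def molecular_weight(sequence: str) -> float:
    """Average molecular mass in daltons (sum of residue masses + one water).

    Raises on an empty sequence or on X / ``*``: an unknown residue has no
    defined mass.
    """
    if not sequence:
        raise ValueError("cannot compute molecular weight of an empty sequence")
    mass = WATER_MASS
    for aa in sequence:
        try:
            mass += RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"no defined mass for residue {aa!r}") from None
    return mass


def net_charge(sequence: str, pH: float, pka: dict | None = None) -> float:
    """Signed net charge at ``pH`` by the Henderson-Hasselbalch equation,
    summing the N-terminus, C-terminus and ionizable side chains (D, E, C, Y
    acidic; H, K, R basic).  Non-ionizable residues (including X) contribute
    nothing."""
    pka = pka or PKA_EMBOSS
    charge = 1.0 / (1.0 + 10.0 ** (pH - pka["nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pka["cterm"] - pH))
    for aa in BASIC:
        n = sequence.count(aa)
        if n:
            charge += n / (1.0 + 10.0 ** (pH - pka[aa]))
    for aa in ACIDIC:
        n = sequence.count(aa)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka[aa] - pH))
    return charge


def isoelectric_point(sequence: str, tol: float = 1e-4, pka: dict | None = None) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The net charge is strictly decreasing in pH, so the root is unique; the
    termini guarantee at least one acidic and one basic group.
    """
    lo, hi = 0.0, 14.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        c = net_charge(sequence, mid, pka)
        if abs(c) < tol and hi - lo < 1e-6:
            break
        if c > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def phys_props(
    protein_id: str,
    sequence: str,
    domain_coverage: float | None = None,
    pka: dict | None = None,
) -> PhysProps:
    return PhysProps(
        protein_id=protein_id,
        mw_kda=molecular_weight(sequence) / 1000.0,
        pi=isoelectric_point(sequence, pka=pka),
        domain_coverage=domain_coverage,
    )
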