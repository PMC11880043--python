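"""Physicochemical characterization: molecular weight, net charge and
isoelectric point, residue composition, and hydropathy profiles.

The point of these numbers in a QTY design is the *invariance* argument:
Q, T and Y are neutral, so the substitutions add no acidic or basic
residue and the isoelectric point barely moves, while the molecular
weight rises only by the small per-pair mass deltas (L→Q +14.97 Da,
I→T −12.05, V→T +1.97, F→Y +16.00, free-amino-acid scale).

Masses are average (not monoisotopic) residue masses, consistent with the
Expasy Compute pI/MW convention; the isoelectric point uses a
Henderson–Hasselbalch net-charge model with a configurable pKa set
(Bjellqvist/Expasy-compatible by default, EMBOSS as an alternative) and a
bisection root finder.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from .seq_io import STANDARD_AA, SequenceError

__all__ = [
    "ResidueMassTable",
    "PkaTable",
    "AVERAGE_MASSES",
    "PKA_SETS",
    "KYTE_DOOLITTLE",
    "molecular_weight",
    "net_charge",
    "isoelectric_point",
    "hydropathy_profile",
    "composition",
]

# Average residue masses in Da (free amino acid = residue + water).
_AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_WATER = 18.01524


@dataclass(frozen=True)
class ResidueMassTable:
    """Average residue masses (Da) plus the mass of one water."""

    masses: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType(_AVERAGE_RESIDUE_MASS)
    )
    water_mass: float = _WATER
    name: str = "average"

    def free_amino_acid_mass(self, aa: str) -> float:
        """Mass of the free amino acid: residue mass + water."""
        return self.masses[aa] + self.water_mass


AVERAGE_MASSES = ResidueMassTable()


@dataclass(frozen=True)
class PkaTable:
    """Side-chain and terminal pKa values for the ionizable groups.

    Positive groups: N-terminus, K, R, H.  Negative: C-terminus, D, E,
    C, Y.  All values must lie in (0, 14).
    """

    n_term: float
    c_term: float
    side_chain: Mapping[str, float]  # D, E, C, Y, H, K, R
    name: str = "custom"

    POSITIVE = ("K", "R", "H")
    NEGATIVE = ("D", "E", "C", "Y")

    def __post_init__(self) -> None:
        for val in (self.n_term, self.c_term, *self.side_chain.values()):
            if not 0 < val < 14:
                raise ValueError(f"pKa {val} outside (0, 14)")


#: Named pKa sets.  "expasy" is the Bjellqvist set used by the Expasy
#: Compute pI/MW tool (without its charged-neighbour context rules);
#: "emboss" is the EMBOSS iep default.
PKA_SETS: Mapping[str, PkaTable] = MappingProxyType(
    {
        "expasy": PkaTable(
            n_term=7.5,
            c_term=3.55,
            side_chain=MappingProxyType(
                {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
                 "H": 5.98, "K": 10.0, "R": 12.0}
            ),
            name="expasy",
        ),
        "emboss": PkaTable(
            n_term=8.6,
            c_term=3.6,
            side_chain=MappingProxyType(
                {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
                 "H": 6.5, "K": 10.8, "R": 12.5}
            ),
            name="emboss",
        ),
    }
)

#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE: Mapping[str, float] = MappingProxyType(
    {
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
        "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
        "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
        "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    }
)

_SCALES: Mapping[str, Mapping[str, float]] = {"Kyte-Doolittle": KYTE_DOOLITTLE}


def _check_residues(seq: str, allowed, what: str) -> None:
    for i, aa in enumerate(seq, start=1):
        if aa not in allowed:
            raise SequenceError(
                f"residue {aa!r} at position {i} not covered by {what}"
            )


def molecular_weight(seq: str, table: ResidueMassTable = AVERAGE_MASSES) -> float:
    """Average molecular weight in Da: sum of residue masses + one water.

    Additive up to water: MW(a + b) = MW(a) + MW(b) − water.
    """
    if not seq:
        raise SequenceError("empty sequence has no molecular weight")
    _check_residues(seq, table.masses, f"mass table {table.name!r}")
    return sum(table.masses[aa] for aa in seq) + table.water_mass


def net_charge(seq: str, pH: float, table: PkaTable = PKA_SETS["expasy"]) -> float:
    """Henderson–Hasselbalch net charge (elementary charges) at ``pH``.

    charge = Σ_pos 1/(1+10^(pH−pKa)) − Σ_neg 1/(1+10^(pKa−pH)),
    where the positive sum runs over the free N-terminus plus K, R, H side
    chains and the negative sum over the free C-terminus plus D, E, C, Y.
    Strictly decreasing in pH, which makes the isoelectric point unique.
    """
    if not 0 < pH < 14:
        raise ValueError(f"pH {pH} outside (0, 14)")
    if not seq:
        raise SequenceError("empty sequence has no charge")
    _check_residues(seq, STANDARD_AA, "the charge model")
    counts = Counter(seq)
    charge = 1.0 / (1.0 + 10.0 ** (pH - table.n_term))
    charge -= 1.0 / (1.0 + 10.0 ** (table.c_term - pH))
    for aa in PkaTable.POSITIVE:
        if counts[aa]:
            charge += counts[aa] / (1.0 + 10.0 ** (pH - table.side_chain[aa]))
    for aa in PkaTable.NEGATIVE:
        if counts[aa]:
            charge -= counts[aa] / (1.0 + 10.0 ** (table.side_chain[aa] - pH))
    return charge


def isoelectric_point(
    seq: str, table: PkaTable = PKA_SETS["expasy"], tol: float = 1e-4
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    With free termini every peptide has at least one positive and one
    negative group, so the strictly decreasing charge curve has exactly
    one root; bisection converges to ``tol`` pH units.
    """
    lo, hi = 1e-9, 14.0 - 1e-9
    f_lo = net_charge(seq, lo, table)
    if f_lo < 0:  # pathological table; charge already negative at pH≈0
        return lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, table) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def hydropathy_profile(
    seq: str, scale: str = "Kyte-Doolittle", window: int = 19
) -> list[tuple[int, float]]:
    """Sliding-window mean hydropathy.

    Returns ``(center position (1-based), mean score)`` pairs; the window
    must be odd and no longer than the sequence, giving
    ``len(seq) − window + 1`` values.  Windows averaging above ~1.6 on the
    Kyte–Doolittle scale at width 19 are the classic signature of a
    membrane-spanning helix.
    """
    if scale not in _SCALES:
        raise ValueError(f"unknown hydropathy scale {scale!r}")
    values = _SCALES[scale]
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window > len(seq):
        raise ValueError(
            f"window {window} longer than sequence ({len(seq)} residues)"
        )
    _check_residues(seq, values, f"hydropathy scale {scale!r}")
    half = window // 2
    scores = [values[aa] for aa in seq]
    out: list[tuple[int, float]] = []
    running = sum(scores[:window])
    out.append((half + 1, running / window))
    for i in range(1, len(seq) - window + 1):
        running += scores[i + window - 1] - scores[i - 1]
        out.append((i + half + 1, running / window))
    return out


def composition(seq: str) -> dict[str, int]:
    """Exact residue counts; the counts sum to the sequence length."""
    _check_residues(seq, STANDARD_AA, "the standard alphabet")
    return dict(Counter(seq))
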