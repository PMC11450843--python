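"""Monoisotopic mass arithmetic for crosslink-modified core peptides.

Each oxidative side-chain crosslink (biaryl C-C, C-N, or aryl-ether
C-O bridge) removes two hydrogens from the peptide's elemental formula,
so an observed [M+H]+ that is 2n x m(H) below the unmodified peptide's
indicates n modifications. Combined with optional N-terminal
truncation of the core (exoproteolytic trimming is common during
atropopeptide maturation), this yields a small grid of candidate ions
against which HR-MS features of culture extracts are matched in ppm.

m/z of the protonated cation is computed with electron-mass correction:
m([M+H]+) = m(M) + m(proton), where the proton mass already accounts
for the missing electron.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

ELEMENTS = ("C", "H", "N", "O", "S")

#: CODATA/AME monoisotopic masses (u).
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}
PROTON_MASS = 1.007276466879
ELECTRON_MASS = 0.00054857990907


@dataclass(frozen=True)
class ElementalFormula:
    """Integer atom counts over C, H, N, O, S."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0

    def __post_init__(self) -> None:
        for el in ELEMENTS:
            if getattr(self, el) < 0:
                raise ValueError(f"negative {el} count")

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(
            **{el: getattr(self, el) + getattr(other, el) for el in ELEMENTS}
        )

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = {
            el: getattr(self, el) - getattr(other, el) for el in ELEMENTS
        }
        if any(v < 0 for v in counts.values()):
            raise ValueError(f"subtraction yields negative counts: {counts}")
        return ElementalFormula(**counts)

    @property
    def monoisotopic_mass(self) -> float:
        return sum(
            getattr(self, el) * MONOISOTOPIC_MASS[el] for el in ELEMENTS
        )

    def hill(self) -> str:
        """Hill-order formula string (C, H, then alphabetical)."""
        parts = []
        for el in ("C", "H", "N", "O", "S"):
            n = getattr(self, el)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)


WATER = ElementalFormula(H=2, O=1)
H2 = ElementalFormula(H=2)

#: Residue (amino acid minus water) compositions.
RESIDUE_FORMULA = {
    "G": ElementalFormula(C=2, H=3, N=1, O=1),
    "A": ElementalFormula(C=3, H=5, N=1, O=1),
    "S": ElementalFormula(C=3, H=5, N=1, O=2),
    "P": ElementalFormula(C=5, H=7, N=1, O=1),
    "V": ElementalFormula(C=5, H=9, N=1, O=1),
    "T": ElementalFormula(C=4, H=7, N=1, O=2),
    "C": ElementalFormula(C=3, H=5, N=1, O=1, S=1),
    "L": ElementalFormula(C=6, H=11, N=1, O=1),
    "I": ElementalFormula(C=6, H=11, N=1, O=1),
    "N": ElementalFormula(C=4, H=6, N=2, O=2),
    "D": ElementalFormula(C=4, H=5, N=1, O=3),
    "Q": ElementalFormula(C=5, H=8, N=2, O=2),
    "K": ElementalFormula(C=6, H=12, N=2, O=1),
    "E": ElementalFormula(C=5, H=7, N=1, O=3),
    "M": ElementalFormula(C=5, H=9, N=1, O=1, S=1),
    "H": ElementalFormula(C=6, H=7, N=3, O=1),
    "F": ElementalFormula(C=9, H=9, N=1, O=1),
    "R": ElementalFormula(C=6, H=12, N=4, O=1),
    "Y": ElementalFormula(C=9, H=9, N=1, O=2),
    "W": ElementalFormula(C=11, H=10, N=2, O=1),
}


def peptide_formula(seq: str) -> ElementalFormula:
    """Neutral formula of a linear peptide: residue sums plus one water."""
    seq = seq.upper()
    total = WATER
    for aa in seq:
        try:
            total = total + RESIDUE_FORMULA[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r}")
    if not seq:
        raise ValueError("empty peptide")
    return total


def apply_crosslinks(formula: ElementalFormula, n: int) -> ElementalFormula:
    """Remove 2n hydrogens, one H2 per oxidative crosslink."""
    if n < 0:
        raise ValueError("crosslink count must be >= 0")
    return formula - ElementalFormula(H=2 * n)


def mz_protonated(formula: ElementalFormula) -> float:
    """Monoisotopic m/z of [M+H]+ with electron-mass correction."""
    return formula.monoisotopic_mass + PROTON_MASS


def ppm_error(observed: float, calculated: float) -> float:
    """Signed relative error (observed - calculated) in parts per million."""
    if observed <= 0 or calculated <= 0:
        raise ValueError("m/z values must be positive")
    return (observed - calculated) / calculated * 1e6


@dataclass(frozen=True)
class IonCandidate:
    """A candidate [M+H]+ ion of a (possibly truncated) modified core."""

    peptide: str
    n_crosslinks: int
    truncation: int  # N-terminal residues removed from the input core
    formula: ElementalFormula
    mz: float


def candidate_series(
    core: str,
    max_crosslinks: int,
    allow_n_truncations: int = 0,
) -> list[IonCandidate]:
    """All (truncation, crosslink-count) combinations for a core peptide,
    sorted by m/z."""
    core = core.upper()
    if len(core) < 2:
        raise ValueError("core must have at least two residues")
    if allow_n_truncations >= len(core):
        raise ValueError("cannot truncate the entire core")
    out = []
    for trunc in range(allow_n_truncations + 1):
        peptide = core[trunc:]
        base = peptide_formula(peptide)
        for n in range(max_crosslinks + 1):
            formula = apply_crosslinks(base, n)
            out.append(
                IonCandidate(
                    peptide=peptide,
                    n_crosslinks=n,
                    truncation=trunc,
                    formula=formula,
                    mz=round(mz_protonated(formula), 4),
                )
            )
    out.sort(key=lambda c: c.mz)
    return out


def match_observed(
    candidates: Iterable[IonCandidate],
    observed: Iterable[float],
    tolerance_ppm: float = 5.0,
) -> list[tuple[float, IonCandidate, float]]:
    """Pair observed masses with candidates within a ppm tolerance.

    Returns (observed m/z, candidate, signed ppm error) triples, one per
    (observed, candidate) pair inside the tolerance.
    """
    out = []
    for obs in observed:
        for cand in candidates:
            err = ppm_error(obs, cand.mz)
            if abs(err) <= tolerance_ppm:
                out.append((obs, cand, err))
    return out
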