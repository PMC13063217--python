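"""Elemental compositions, masses and fragment-ion series for oligoribonucleotides.

All mass bookkeeping for the package lives here: the element table, the
internal-residue composition table (nucleoside monophosphate minus water, so
each residue carries its own phosphate), terminus chemistry deltas
(2',3'-cyclic phosphate, 3'-linear phosphate, 5'-mono/di/triphosphate, cap
species), negative-mode m/z arithmetic, and the c/y/w/a-B backbone ion series
observed under collisional activation (McLuckey nomenclature).

Conventions
-----------
* A fragment's neutral composition is ``sum(internal residues) + H2O +
  five-prime delta + three-prime delta``.  The cyclic-phosphate delta is
  ``+HPO3 - H2O`` (cyclization of the linear phosphate loses one water), so
  the cyclic and linear variants of the same fragment differ by exactly one
  water.
* Negative-mode ions are deprotonated species: ``m/z = (M - z * m_p) / z``
  with the proton mass, not the hydrogen-atom mass.
* Atomic masses are hard-coded (IUPAC monoisotopic values) for
  reproducibility; the test suite cross-checks them against pyteomics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

__all__ = [
    "ElementalComposition",
    "TheoreticalIon",
    "MONOISOTOPIC_ELEMENT_MASSES",
    "AVERAGE_ELEMENT_MASSES",
    "PROTON_MASS",
    "H2O",
    "HPO3",
    "RESIDUE_COMPOSITIONS",
    "NUCLEOBASE_COMPOSITIONS",
    "FIVE_PRIME_LABELS",
    "THREE_PRIME_LABELS",
    "residue_mass",
    "fragment_composition",
    "fragment_mass",
    "monoisotopic_mass",
    "average_mass",
    "mz",
    "neutral_mass_from_mz",
    "ppm_error",
    "ms2_ions",
    "methylate_2prime",
]

# Monoisotopic masses of the most abundant isotope (IUPAC), and standard
# atomic weights for average masses.  Only the elements occurring in
# ribonucleotides and caps are needed.
MONOISOTOPIC_ELEMENT_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
}

AVERAGE_ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.973762,
}

#: Mass of a proton, used for (de)protonation in negative-mode m/z.
PROTON_MASS: float = 1.00727646688

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementalComposition(dict):
    """A chemical formula as an element -> count mapping.

    Supports element-wise addition, subtraction (raising if any count would
    go negative) and integer scaling.  Construct from a formula string
    (``"C10H12N5O6P"``), a mapping, or keyword counts.
    """

    def __init__(self, formula: str | Mapping[str, int] = "", **counts: int):
        super().__init__()
        if isinstance(formula, Mapping):
            for el, n in formula.items():
                self._bump(el, n)
        elif formula:
            self._parse(formula)
        for el, n in counts.items():
            self._bump(el, n)

    def _parse(self, formula: str) -> None:
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = m.end()
            self._bump(m.group(1), int(m.group(2) or 1))
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")

    def _bump(self, element: str, n: int) -> None:
        if n < 0:
            raise ValueError(f"negative count for element {element}")
        if n:
            self[element] = self.get(element, 0) + n

    def __add__(self, other: Mapping[str, int]) -> "ElementalComposition":
        out = ElementalComposition(self)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return ElementalComposition({el: n for el, n in out.items() if n})

    def __sub__(self, other: Mapping[str, int]) -> "ElementalComposition":
        out = dict(self)
        for el, n in other.items():
            left = out.get(el, 0) - n
            if left < 0:
                raise ValueError(
                    f"subtraction yields negative count for element {el}"
                )
            out[el] = left
        return ElementalComposition({el: n for el, n in out.items() if n})

    def __mul__(self, k: int) -> "ElementalComposition":
        if not isinstance(k, int) or k < 0:
            raise ValueError("compositions scale by non-negative integers")
        return ElementalComposition({el: n * k for el, n in self.items()})

    __rmul__ = __mul__

    @property
    def monoisotopic(self) -> float:
        return monoisotopic_mass(self)

    @property
    def average(self) -> float:
        return average_mass(self)

    def formula(self) -> str:
        """Formula string in Hill order (C, H, then alphabetical)."""
        order = sorted(self, key=lambda e: (e != "C", e != "H", e))
        return "".join(
            f"{el}{self[el]}" if self[el] != 1 else el for el in order
        )


def monoisotopic_mass(comp: Mapping[str, int]) -> float:
    """Sum of count x most-abundant-isotope mass over the composition."""
    try:
        return sum(MONOISOTOPIC_ELEMENT_MASSES[el] * n for el, n in comp.items())
    except KeyError as exc:  # pragma: no cover - guard
        raise ValueError(f"unknown element {exc.args[0]!r}") from exc


def average_mass(comp: Mapping[str, int]) -> float:
    """Average mass using standard atomic weights."""
    try:
        return sum(AVERAGE_ELEMENT_MASSES[el] * n for el, n in comp.items())
    except KeyError as exc:  # pragma: no cover - guard
        raise ValueError(f"unknown element {exc.args[0]!r}") from exc


H2O = ElementalComposition("H2O")
HPO3 = ElementalComposition("HPO3")
_CH2 = ElementalComposition("CH2")

# Internal residues: nucleoside monophosphate - H2O.  'Y' denotes
# N1-methylpseudouridine (m1-psi, a uridine isomer plus a methyl, so its
# composition is U + CH2).  Lowercase symbols are the 2'-O-methyl variants
# (ribose methylation, + CH2), following oligo-synthesis shorthand.
RESIDUE_COMPOSITIONS: dict[str, ElementalComposition] = {
    "A": ElementalComposition("C10H12N5O6P"),
    "C": ElementalComposition("C9H12N3O7P"),
    "G": ElementalComposition("C10H12N5O7P"),
    "U": ElementalComposition("C9H11N2O8P"),
    "Y": ElementalComposition("C10H13N2O8P"),
}
for _b in ("A", "C", "G", "U", "Y"):
    RESIDUE_COMPOSITIONS[_b.lower()] = RESIDUE_COMPOSITIONS[_b] + _CH2

# Free nucleobase molecules, lost in a-B ions.  The methylated base of 'Y'
# is modelled as 1-methyluracil; ribose 2'-O-methylation does not change the
# base, so lowercase symbols share their parent's base.
NUCLEOBASE_COMPOSITIONS: dict[str, ElementalComposition] = {
    "A": ElementalComposition("C5H5N5"),
    "C": ElementalComposition("C4H5N3O"),
    "G": ElementalComposition("C5H5N5O"),
    "U": ElementalComposition("C4H4N2O2"),
    "Y": ElementalComposition("C5H6N2O2"),
}
for _b in ("A", "C", "G", "U", "Y"):
    NUCLEOBASE_COMPOSITIONS[_b.lower()] = NUCLEOBASE_COMPOSITIONS[_b]

#: Recognised 5' terminus labels (cap species are passed as objects).
FIVE_PRIME_LABELS = ("OH", "p", "pp", "ppp")
#: Recognised 3' terminus labels.
THREE_PRIME_LABELS = ("OH", "cyclic_phosphate", "linear_phosphate")

_FIVE_PRIME_DELTAS: dict[str, ElementalComposition] = {
    "OH": ElementalComposition(),
    "p": HPO3,
    "pp": 2 * HPO3,
    "ppp": 3 * HPO3,
}

_H2O_MASS = H2O.monoisotopic
_HPO3_MASS = HPO3.monoisotopic
_CH2_MASS = _CH2.monoisotopic


@lru_cache(maxsize=None)
def residue_mass(symbol: str) -> float:
    """Monoisotopic mass of one internal residue."""
    try:
        return RESIDUE_COMPOSITIONS[symbol].monoisotopic
    except KeyError:
        raise ValueError(f"unknown residue symbol {symbol!r}") from None


def methylate_2prime(sequence: str, n: int) -> str:
    """Convert the first ``n`` residues to their 2'-O-methyl (lowercase) form."""
    return sequence[:n].lower() + sequence[n:]


def _five_prime_delta(five_prime) -> tuple[ElementalComposition, int]:
    """Resolve a 5' terminus spec into (composition delta, residues methylated).

    ``five_prime`` is either one of :data:`FIVE_PRIME_LABELS` or a cap-species
    object exposing ``formula_delta`` and ``covers_first_n``.
    """
    if isinstance(five_prime, str):
        try:
            return _FIVE_PRIME_DELTAS[five_prime], 0
        except KeyError:
            raise ValueError(f"unknown 5' terminus {five_prime!r}") from None
    return five_prime.formula_delta, int(getattr(five_prime, "covers_first_n", 0))


def _three_prime_parts(three_prime: str) -> tuple[ElementalComposition, ElementalComposition]:
    """(add, remove) composition pair for a 3' terminus."""
    if three_prime == "OH":
        return ElementalComposition(), ElementalComposition()
    if three_prime == "linear_phosphate":
        return HPO3, ElementalComposition()
    if three_prime == "cyclic_phosphate":
        return HPO3, H2O
    raise ValueError(f"unknown 3' terminus {three_prime!r}")


def fragment_composition(
    sequence: str,
    five_prime="OH",
    three_prime: str = "cyclic_phosphate",
) -> ElementalComposition:
    """Neutral elemental composition of an oligoribonucleotide fragment.

    Parameters
    ----------
    sequence
        Residue symbols drawn from :data:`RESIDUE_COMPOSITIONS`.
    five_prime
        ``"OH"``, ``"p"``, ``"pp"``, ``"ppp"`` or a cap-species object.  A
        cap implies 2'-O-methylation of its ``covers_first_n`` leading
        transcript residues, applied here.
    three_prime
        ``"OH"``, ``"cyclic_phosphate"`` or ``"linear_phosphate"``.
    """
    if not sequence:
        raise ValueError("empty fragment sequence")
    delta5, n_methyl = _five_prime_delta(five_prime)
    seq = methylate_2prime(sequence, n_methyl) if n_methyl else sequence
    comp = ElementalComposition(H2O)
    for sym in seq:
        try:
            comp = comp + RESIDUE_COMPOSITIONS[sym]
        except KeyError:
            raise ValueError(f"unknown residue symbol {sym!r}") from None
    comp = comp + delta5
    add3, remove3 = _three_prime_parts(three_prime)
    return comp + add3 - remove3


def fragment_mass(
    sequence: str,
    five_prime="OH",
    three_prime: str = "cyclic_phosphate",
) -> float:
    """Monoisotopic neutral mass of a fragment (fast float path)."""
    delta5, n_methyl = _five_prime_delta(five_prime)
    mass = _H2O_MASS + delta5.monoisotopic + n_methyl * _CH2_MASS
    for sym in sequence:
        mass += residue_mass(sym)
    if three_prime == "cyclic_phosphate":
        mass += _HPO3_MASS - _H2O_MASS
    elif three_prime == "linear_phosphate":
        mass += _HPO3_MASS
    elif three_prime != "OH":
        raise ValueError(f"unknown 3' terminus {three_prime!r}")
    return mass


def mz(neutral_mass: float, charge: int) -> float:
    """Negative-mode m/z of a neutral at charge magnitude ``charge``.

    The species is the ``charge``-fold deprotonated anion:
    ``(M - z * m_p) / z``.
    """
    if charge == 0:
        raise ValueError("charge must be a non-zero magnitude")
    z = abs(int(charge))
    return (neutral_mass - z * PROTON_MASS) / z


def neutral_mass_from_mz(mz_value: float, charge: int) -> float:
    """Invert :func:`mz`: neutral mass from an observed negative-mode peak."""
    z = abs(int(charge))
    if z == 0:
        raise ValueError("charge must be a non-zero magnitude")
    return mz_value * z + z * PROTON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return (observed - theoretical) / theoretical * 1e6


@dataclass(frozen=True, slots=True)
class TheoreticalIon:
    """One predicted backbone fragment ion.

    ``index`` is the cleavage ordinal counted from the relevant terminus
    (5' for c/a/a-B, 3' for y/w); ``charge`` is the magnitude of the
    negative charge.
    """

    series: str
    index: int
    charge: int
    neutral_mass: float
    mz: float


_DEFAULT_SERIES = ("c", "y", "w", "a-B")


def ms2_ions(
    sequence: str,
    five_prime="OH",
    three_prime: str = "cyclic_phosphate",
    series: Iterable[str] = _DEFAULT_SERIES,
    charges: Iterable[int] = (1, 2),
) -> list[TheoreticalIon]:
    """Theoretical c/y/w/a-B ions for every backbone cleavage ordinal.

    Definitions (chosen so the complementarity identities hold exactly):
    ``c_i`` is the 5' piece retaining the internucleotide phosphate
    (3'-linear-phosphate end), ``y_j`` the 3' piece with 5'-OH,
    ``w_j = y_j + HPO3`` (5'-phosphate), ``a_i = c_i - HPO3`` and
    ``a-B_i`` additionally loses the 3'-terminal nucleobase of the piece as
    the free base.  For a precursor of neutral mass M:
    ``c_i + y_(n-i) = M + H2O`` and ``w_j - y_j = HPO3`` for all ordinals.

    Fragments shorter than two residues yield no ions.
    """
    n = len(sequence)
    if n < 2:
        return []
    delta5, n_methyl = _five_prime_delta(five_prime)
    seq = methylate_2prime(sequence, n_methyl) if n_methyl else sequence
    res = [residue_mass(s) for s in seq]
    prefix = [0.0]
    for m in res:
        prefix.append(prefix[-1] + m)
    total = prefix[-1]
    add3, remove3 = _three_prime_parts(three_prime)
    d3 = add3.monoisotopic - remove3.monoisotopic
    d5 = delta5.monoisotopic

    series = tuple(series)
    charges = tuple(sorted({abs(int(z)) for z in charges}))
    out: list[TheoreticalIon] = []
    for i in range(1, n):
        # 5'-side ordinal i pairs with 3'-side ordinal j = n - i
        c_mass = prefix[i] + _H2O_MASS + d5
        y_mass = (total - prefix[i]) + _H2O_MASS + d3
        neutral = {
            "c": c_mass,
            "a": c_mass - _HPO3_MASS,
            "a-B": c_mass
            - _HPO3_MASS
            - NUCLEOBASE_COMPOSITIONS[seq[i - 1]].monoisotopic,
            "y": y_mass,
            "w": y_mass + _HPO3_MASS,
        }
        for s in series:
            if s not in neutral:
                raise ValueError(f"unknown ion series {s!r}")
            mass = neutral[s]
            idx = i if s in ("c", "a", "a-B") else n - i
            for z in charges:
                m_over_z = mz(mass, z)
                if m_over_z > 0:
                    out.append(TheoreticalIon(s, idx, z, mass, m_over_z))
    return out
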