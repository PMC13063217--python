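"""Multi-attribute monitoring: 5' capping efficiency and poly(A) tail length.

Under complete-digest conditions the 5'-terminal fragment elutes as a set of
species (capped plus uncapped tri-/di-/monophosphate forms) whose relative
MS1 areas give the capping efficiency, while the released 3' poly(A) tail
fragment appears as a ladder of deconvoluted neutral masses spaced by one AMP
residue (~329.05 Da) encoding tail length and heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .masses import PROTON_MASS, residue_mass

__all__ = [
    "FivePrimeSpecies",
    "PolyATailDistribution",
    "A_RESIDUE_MASS",
    "cap_efficiency",
    "polyA_length_from_mass",
    "polyA_distribution",
    "deconvolve_adjacent_pair",
    "species_table_from_frame",
]

#: Monoisotopic mass of one internal AMP residue.
A_RESIDUE_MASS: float = residue_mass("A")


@dataclass(frozen=True)
class FivePrimeSpecies:
    """One row of a 5'-terminal species table."""

    label: str
    theoretical_mass: float
    area: float
    capped: bool

    def __post_init__(self):
        if self.area < 0:
            raise ValueError("areas must be >= 0")


def species_table_from_frame(frame: pd.DataFrame) -> list[FivePrimeSpecies]:
    """Build a species table from a CSV-derived DataFrame.

    Expects columns ``label``, ``area``, ``capped`` and optionally
    ``theoretical_mass``.
    """
    out = []
    for _, row in frame.iterrows():
        out.append(
            FivePrimeSpecies(
                label=str(row["label"]),
                theoretical_mass=float(row.get("theoretical_mass", 0.0) or 0.0),
                area=float(row["area"]),
                capped=bool(row["capped"]),
            )
        )
    return out


def cap_efficiency(table: Sequence[FivePrimeSpecies]) -> float:
    """Capping efficiency as a percentage, by relative quantification.

    100 x (sum of capped-species areas) / (sum of all areas).  The result is
    scale-invariant and bounded in [0, 100].  All-zero areas are an error.
    """
    labels = [s.label for s in table]
    if len(set(labels)) != len(labels):
        raise ValueError("species labels must be unique")
    total = sum(s.area for s in table)
    if total <= 0:
        raise ValueError("total 5' species area is zero")
    capped = sum(s.area for s in table if s.capped)
    return 100.0 * capped / total


def polyA_length_from_mass(
    neutral_mass: float,
    base_mass: float,
    residue_mass_da: float = A_RESIDUE_MASS,
    tol: float = 0.25,
) -> int | None:
    """Assign a tail length to one deconvoluted neutral mass.

    ``base_mass`` is the mass of the tail fragment at n = 0 (termini plus
    any linker residues).  Returns the nearest integer residue count n if
    the residual |mass - (base + n x residue)| is within ``tol`` and
    n >= 0, else None (no assignment).
    """
    if residue_mass_da <= 0:
        raise ValueError("residue mass must be positive")
    n = round((neutral_mass - base_mass) / residue_mass_da)
    if n < 0:
        return None
    if abs(neutral_mass - (base_mass + n * residue_mass_da)) > tol:
        return None
    return int(n)


@dataclass
class PolyATailDistribution:
    """Poly(A) tail length distribution recovered from a mass ladder."""

    lengths: list[tuple[int, float]]  # (n, abundance), sorted by n
    base_mass: float

    def __post_init__(self):
        if any(a < 0 for _, a in self.lengths):
            raise ValueError("abundances must be >= 0")
        self.lengths = sorted(self.lengths)

    @property
    def modal_length(self) -> int:
        """Tail length with maximal abundance (smallest n on ties)."""
        best_n, best_a = self.lengths[0]
        for n, a in self.lengths[1:]:
            if a > best_a:
                best_n, best_a = n, a
        return best_n

    @property
    def total_intensity(self) -> float:
        return sum(a for _, a in self.lengths)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.lengths, columns=["length_nt", "abundance"])


def polyA_distribution(
    peaks: Iterable[tuple[float, float]],
    base_mass: float,
    tol: float = 0.25,
    residue_mass_da: float = A_RESIDUE_MASS,
) -> PolyATailDistribution:
    """Aggregate a deconvoluted mass ladder into a length distribution.

    Each (neutral mass, intensity) peak is assigned a length or dropped;
    intensities are summed per length.  Unassignable-everything is an error
    carrying the residuals as a diagnostic.  Total output intensity never
    exceeds input intensity (drops only).
    """
    peaks = list(peaks)
    if not peaks:
        raise ValueError("at least one peak required")
    acc: dict[int, float] = {}
    residuals = []
    for mass, intensity in peaks:
        n = polyA_length_from_mass(mass, base_mass, residue_mass_da, tol)
        if n is None:
            frac = (mass - base_mass) / residue_mass_da
            residuals.append(round(frac - round(frac), 3))
            continue
        acc[n] = acc.get(n, 0.0) + float(intensity)
    if not acc:
        raise ValueError(
            "no peak could be assigned a tail length; "
            f"fractional-residue residuals: {residuals}"
        )
    return PolyATailDistribution(lengths=sorted(acc.items()), base_mass=base_mass)


def deconvolve_adjacent_pair(mz1: float, mz2: float) -> tuple[float, int]:
    """Neutral mass and charge from two adjacent negative-mode charge states.

    Given two m/z values ``mz1 > mz2`` assumed to be consecutive charge
    states z and z+1 of the same neutral M (deprotonated ions), solves
    z = (mz2 + m_p) / (mz1 - mz2) and returns (M, z).  This adjacent-pair
    solver is approximate — it ignores isotope structure and requires truly
    consecutive states — and is meant as a convenience for simple charge
    envelopes, not a replacement for full deconvolution.
    """
    if mz1 <= mz2:
        raise ValueError("expected mz1 > mz2 (lower charge first)")
    z = round((mz2 + PROTON_MASS) / (mz1 - mz2))
    if z < 1:
        raise ValueError("inferred charge < 1; peaks are not adjacent states")
    M = z * (mz1 + PROTON_MASS)
    return M, int(z)
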