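"""In-silico (partial) ribonuclease digestion of mRNA constructs.

RNase T1 cleaves single-stranded RNA 3' of guanosine, leaving a 2',3'-cyclic
phosphate on the upstream product and a 5'-OH on the downstream product; the
cyclic phosphate slowly hydrolyses to a 3'-linear phosphate.  A *partial*
digest leaves missed cleavages, producing long overlapping fragments that are
far more often unique within the transcript — the property the mapping layer
relies on.

This module enumerates theoretical digest products with their termini
chemistry, locates fragment placements in a target sequence, and classifies
uniqueness (unique / nonunique / nonspecific).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .construct import MrnaConstruct
from .masses import fragment_mass

__all__ = [
    "EnzymeSpec",
    "RNASE_T1",
    "ENZYMES",
    "TheoreticalFragment",
    "UniquenessClass",
    "cleavage_sites",
    "enumerate_fragments",
    "locate_occurrences",
    "classify_uniqueness",
    "fragments_to_frame",
]

#: Default missed-cleavage ceiling for partial-digest candidate generation.
DEFAULT_MAX_MISSED = 8
#: Default processing limit on candidate neutral mass (Da).
DEFAULT_MASS_CAP = 30_000.0


@dataclass(frozen=True)
class EnzymeSpec:
    """Cleavage specificity and termini chemistry of a ribonuclease."""

    name: str
    cleaves_after: frozenset[str]
    leaves_upstream: tuple[str, ...] = ("cyclic_phosphate", "linear_phosphate")
    leaves_downstream: str = "OH"

    def __post_init__(self):
        if not self.cleaves_after:
            raise ValueError("cleaves_after must be non-empty")
        if not self.leaves_upstream:
            raise ValueError("leaves_upstream must be non-empty")


RNASE_T1 = EnzymeSpec(name="RNase T1", cleaves_after=frozenset("G"))
ENZYMES = {"T1": RNASE_T1, "RNase T1": RNASE_T1}


@dataclass(frozen=True, slots=True)
class TheoreticalFragment:
    """One theoretical digest product.

    ``start``/``end`` are 1-based inclusive positions on the construct;
    ``sequence`` is the construct substring with global substitutions
    applied.  ``five_prime`` is "OH", "p", "pp", "ppp" or a cap label;
    position-1 fragments may carry ``cap`` as the species object.
    """

    start: int
    end: int
    sequence: str
    five_prime: str
    three_prime: str
    missed_cleavages: int
    neutral_mass: float
    cap: object = field(default=None, compare=False)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class UniquenessClass:
    """Placement-count classification of an observed fragment sequence."""

    value: str  # unique | nonunique | nonspecific
    occurrence_count: int

    def __post_init__(self):
        if self.value not in ("unique", "nonunique", "nonspecific"):
            raise ValueError(f"bad uniqueness value {self.value!r}")
        if self.value == "unique" and self.occurrence_count != 1:
            raise ValueError("unique requires occurrence_count == 1")


def cleavage_sites(sequence: str, enzyme: EnzymeSpec = RNASE_T1) -> list[int]:
    """1-based positions p where the bond 3' of residue p is cleavable.

    A cleavable residue at the last position yields no site (there is no
    bond 3' of it inside the molecule).
    """
    cut = enzyme.cleaves_after
    return [i + 1 for i in range(len(sequence) - 1) if sequence[i] in cut]


def _native_five_prime(construct: MrnaConstruct) -> tuple[str, object]:
    native = construct.five_prime_native
    if isinstance(native, str):
        return native, None
    return native.label, native


def enumerate_fragments(
    construct: MrnaConstruct,
    enzyme: EnzymeSpec = RNASE_T1,
    max_missed: int = DEFAULT_MAX_MISSED,
    termini: Sequence[str] = ("cyclic_phosphate", "linear_phosphate"),
    mass_cap: float | None = DEFAULT_MASS_CAP,
) -> list[TheoreticalFragment]:
    """Enumerate every theoretical (partial) digest product.

    Fragments are delimited by the construct ends and/or cleavage sites,
    with at most ``max_missed`` uncleaved internal sites.  Each internal
    fragment is expanded over the allowed 3' termini chemistries (cyclic
    phosphate is the direct transesterification product; the linear
    3'-phosphate is its hydrolysed form, a variable modification).  A
    fragment ending at the construct 3' end keeps the native 3'-OH; a
    fragment starting at position 1 carries the native 5' end (cap species
    or triphosphate), all others 5'-OH from the enzyme mechanism.

    Candidates above ``mass_cap`` Da are dropped.  Output is sorted by
    (start, end, three_prime).
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    for t in termini:
        if t not in ("cyclic_phosphate", "linear_phosphate"):
            raise ValueError(f"unsupported 3' terminus option {t!r}")

    seq = construct.modified_sequence
    L = len(seq)
    sites = cleavage_sites(seq, enzyme)
    boundaries = [0] + sites + [L]
    native5_label, native5_obj = _native_five_prime(construct)

    out: list[TheoreticalFragment] = []
    nb = len(boundaries)
    for i in range(nb - 1):
        start = boundaries[i] + 1
        for j in range(i + 1, min(i + 2 + max_missed, nb)):
            end = boundaries[j]
            missed = j - i - 1
            frag_seq = seq[start - 1 : end]
            if start == 1:
                fp_label, fp = native5_label, (native5_obj or native5_label)
            else:
                fp_label, fp = "OH", "OH"
            if end == L:
                three_options = ("OH",)
            else:
                three_options = tuple(termini)
            for tp in three_options:
                mass = fragment_mass(frag_seq, fp, tp)
                if mass_cap is not None and mass > mass_cap:
                    continue
                out.append(
                    TheoreticalFragment(
                        start=start,
                        end=end,
                        sequence=frag_seq,
                        five_prime=fp_label,
                        three_prime=tp,
                        missed_cleavages=missed,
                        neutral_mass=mass,
                        cap=native5_obj if start == 1 else None,
                    )
                )
    out.sort(key=lambda f: (f.start, f.end, f.three_prime))
    return out


def locate_occurrences(fragment_sequence: str, target: str) -> list[tuple[int, int]]:
    """All 1-based placements of a fragment in a target, overlaps allowed."""
    if not fragment_sequence:
        raise ValueError("fragment sequence must be non-empty")
    hits = []
    i = target.find(fragment_sequence)
    while i != -1:
        hits.append((i + 1, i + len(fragment_sequence)))
        i = target.find(fragment_sequence, i + 1)
    return hits


def _placement_specific(
    fragment: TheoreticalFragment,
    placement: tuple[int, int],
    target: str,
    enzyme: EnzymeSpec,
) -> bool:
    """Is a placement compatible with the enzyme's termini chemistry?

    The 5' side must be the construct start or be preceded by a cleavable
    residue; a fragment claiming a cleaved 3' end (cyclic/linear phosphate)
    must end in a cleavable residue, while a 3'-OH end must sit at the
    construct 3' terminus.
    """
    a, b = placement
    if a > 1 and target[a - 2] not in enzyme.cleaves_after:
        return False
    if fragment.three_prime == "OH":
        return b == len(target)
    return target[b - 1] in enzyme.cleaves_after


def classify_uniqueness(
    fragment: TheoreticalFragment,
    construct: MrnaConstruct,
    enzyme: EnzymeSpec = RNASE_T1,
) -> UniquenessClass:
    """Count placements of the fragment sequence in the full construct.

    Occurrence counting uses the complete sequence including the poly(A)
    tail, since uniqueness must reflect the real ambiguity an identification
    faces.  A sequence whose required termini are incompatible with the
    enzyme chemistry at every placement is *nonspecific*.
    """
    target = construct.modified_sequence
    placements = locate_occurrences(fragment.sequence, target)
    count = len(placements)
    if count == 0 or not any(
        _placement_specific(fragment, p, target, enzyme) for p in placements
    ):
        return UniquenessClass("nonspecific", count)
    if count == 1:
        return UniquenessClass("unique", 1)
    return UniquenessClass("nonunique", count)


def fragments_to_frame(fragments: Iterable[TheoreticalFragment]) -> pd.DataFrame:
    """Fragment table as a DataFrame (CSV external interface)."""
    return pd.DataFrame(
        [
            {
                "start": f.start,
                "end": f.end,
                "sequence": f.sequence,
                "five_prime": f.five_prime,
                "three_prime": f.three_prime,
                "missed_cleavages": f.missed_cleavages,
                "neutral_mass": f.neutral_mass,
            }
            for f in fragments
        ]
    )
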