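"""Annotated mRNA constructs: sequence, 5' cap, global substitutions, poly(A).

An in vitro transcribed (IVT) mRNA is represented by its canonical sequence
over {A,C,G,U} plus annotations that matter for mass spectrometry: the 5' cap
species, a global modified-nucleotide substitution (e.g. every U transcribed
as N1-methylpseudouridine), and the poly(A) tail interval(s), which are
excluded from the sequence-coverage denominator.

Coordinates are 1-based inclusive throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .masses import ElementalComposition, RESIDUE_COMPOSITIONS

__all__ = [
    "CapSpecies",
    "CAP1_AG",
    "MrnaConstruct",
    "read_mrna_construct",
    "effective_length",
    "make_decoy",
    "construct_summary",
]

logger = logging.getLogger(__name__)

CANONICAL_BASES = frozenset("ACGU")

#: Aliases accepted for modified residue symbols in annotations.
RESIDUE_ALIASES = {
    "m1Y": "Y",
    "m1psi": "Y",
    "m1Ψ": "Y",
    "psi": "Y",
    "Ψ": "Y",
}


@dataclass(frozen=True)
class CapSpecies:
    """A 5' cap structure described by its composition delta.

    ``formula_delta`` is the elemental composition added to the transcript 5'
    end relative to a plain 5'-OH.  ``covers_first_n`` counts leading
    transcript residues whose 2'-O-methylation the cap species implies
    (1 for a Cap1 structure, 0 for bare ppp/pp/p ends).
    """

    label: str
    formula_delta: ElementalComposition
    covers_first_n: int = 0

    def __post_init__(self):
        if self.covers_first_n < 0:
            raise ValueError("covers_first_n must be >= 0")


#: Cap1 as installed by a CleanCap-AG style reagent:
#: m7G(5')ppp(5')(2'OMeA)pG...  The delta is the 7-methylguanosine plus the
#: triphosphate bridge (minus the condensation water); the 2'-O-methyl on the
#: +1 residue is carried by ``covers_first_n``.
CAP1_AG = CapSpecies(
    label="Cap1-AG",
    formula_delta=ElementalComposition("C11H16N5O13P3"),
    covers_first_n=1,
)

KNOWN_CAPS = {CAP1_AG.label: CAP1_AG}


@dataclass
class MrnaConstruct:
    """An annotated mRNA construct.

    Parameters
    ----------
    name
        Free-text identifier.
    sequence
        RNA string over {A,C,G,U}; positions are 1-based.
    cap
        5' cap species, or None for an uncapped (5'-triphosphate) transcript.
    substitutions
        Global base substitutions applied at transcription, canonical base ->
        modified residue symbol (e.g. ``{"U": "Y"}`` for full m1-psi
        substitution).
    polyA_segments
        Disjoint, sorted 1-based inclusive intervals annotated as poly(A)
        tail.  A split tail (e.g. 30 + 70 A with a linker) uses two segments.
    """

    name: str
    sequence: str
    cap: CapSpecies | None = None
    substitutions: dict[str, str] = field(default_factory=dict)
    polyA_segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - CANONICAL_BASES
        if bad:
            raise ValueError(f"non-ACGU symbols in sequence: {sorted(bad)}")
        subs = {}
        for k, v in self.substitutions.items():
            if k not in CANONICAL_BASES:
                raise ValueError(f"substitution key {k!r} is not a canonical base")
            v = RESIDUE_ALIASES.get(v, v)
            if v not in RESIDUE_COMPOSITIONS:
                raise ValueError(f"unknown modified residue symbol {v!r}")
            subs[k] = v
        self.substitutions = subs
        segs = [(int(a), int(b)) for a, b in self.polyA_segments]
        if segs != sorted(segs):
            raise ValueError("polyA_segments must be sorted")
        last_end = 0
        for a, b in segs:
            if not (1 <= a <= b <= len(self.sequence)):
                raise ValueError(f"poly(A) segment ({a},{b}) out of bounds")
            if a <= last_end:
                raise ValueError("polyA_segments must be disjoint")
            last_end = b
            seg = self.sequence[a - 1 : b]
            if seg.count("A") / len(seg) < 0.90:
                raise ValueError(
                    f"poly(A) segment ({a},{b}) is <90% A residues"
                )
        self.polyA_segments = segs

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def modified_sequence(self) -> str:
        """Sequence with the global substitutions applied."""
        if not self.substitutions:
            return self.sequence
        table = str.maketrans(self.substitutions)
        return self.sequence.translate(table)

    @property
    def five_prime_native(self):
        """The transcript's native 5' terminus: the cap, or triphosphate."""
        return self.cap if self.cap is not None else "ppp"

    def polyA_mask(self) -> np.ndarray:
        """Boolean vector (index 0 = position 1) marking poly(A) positions."""
        mask = np.zeros(self.length, dtype=bool)
        for a, b in self.polyA_segments:
            mask[a - 1 : b] = True
        return mask

    def effective_length(self) -> int:
        """Construct length excluding the annotated poly(A) tail."""
        return self.length - sum(b - a + 1 for a, b in self.polyA_segments)


def effective_length(construct: MrnaConstruct) -> int:
    """Length of the coverage denominator: all non-poly(A) positions."""
    return construct.effective_length()


def _resolve_cap(cap) -> CapSpecies | None:
    if cap is None or isinstance(cap, CapSpecies):
        return cap
    if isinstance(cap, str):
        if cap in KNOWN_CAPS:
            return KNOWN_CAPS[cap]
        raise ValueError(
            f"unknown cap label {cap!r}; known: {sorted(KNOWN_CAPS)}"
        )
    if isinstance(cap, dict):
        return CapSpecies(
            label=cap["label"],
            formula_delta=ElementalComposition(cap["formula_delta"]),
            covers_first_n=int(cap.get("covers_first_n", 0)),
        )
    raise TypeError(f"cannot interpret cap annotation {cap!r}")


def read_mrna_construct(fasta_path, annotation=None) -> MrnaConstruct:
    """Read a single-record FASTA plus an annotation block.

    ``annotation`` may be None, a dict, or a path to a YAML file with keys
    ``cap`` (label, dict or null), ``substitutions`` (e.g. ``{U: m1Y}``) and
    ``polyA_segments`` (list of [start, end] 1-based inclusive pairs).

    T residues in the FASTA (DNA-template storage) are transliterated to U
    with a logged warning.  A multi-record FASTA is an error.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"expected exactly one FASTA record, found {len(records)}"
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    if "T" in seq:
        logger.warning(
            "FASTA %s contains T residues; transliterating to U", fasta_path
        )
        seq = seq.replace("T", "U")

    if annotation is None:
        ann = {}
    elif isinstance(annotation, (str, Path)):
        with open(annotation) as fh:
            ann = yaml.safe_load(fh) or {}
    else:
        ann = dict(annotation)

    return MrnaConstruct(
        name=ann.get("name", rec.id),
        sequence=seq,
        cap=_resolve_cap(ann.get("cap")),
        substitutions=dict(ann.get("substitutions") or {}),
        polyA_segments=[tuple(x) for x in (ann.get("polyA_segments") or [])],
    )


def make_decoy(construct: MrnaConstruct, seed: int) -> MrnaConstruct:
    """Length- and composition-matched decoy sequence.

    The decoy is a uniform random permutation of the construct's residue
    multiset, so length and the exact count of each base (hence GC content)
    are preserved by construction.  Poly(A) annotation and cap are dropped;
    the substitution model is kept so decoy candidates compete under the
    same chemistry.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list(construct.sequence))
    shuffled = letters[rng.permutation(len(letters))]
    return MrnaConstruct(
        name=f"{construct.name}-decoy{seed}",
        sequence="".join(shuffled),
        cap=None,
        substitutions=dict(construct.substitutions),
        polyA_segments=[],
    )


def construct_summary(construct: MrnaConstruct) -> pd.DataFrame:
    """One-row summary table (CSV-friendly) of a construct."""
    seq = construct.sequence
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    return pd.DataFrame(
        [
            {
                "name": construct.name,
                "length_nt": construct.length,
                "effective_length_nt": construct.effective_length(),
                "gc_fraction": round(gc, 4),
                "cap": construct.cap.label if construct.cap else "none",
                "substitutions": ";".join(
                    f"{k}>{v}" for k, v in sorted(construct.substitutions.items())
                ),
                "polyA_segments": ";".join(
                    f"{a}-{b}" for a, b in construct.polyA_segments
                ),
            }
        ]
    )
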