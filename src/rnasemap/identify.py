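"""Matching observed MS data to theoretical digest fragments.

MS1 neutral masses (deconvoluted peak tables) or m/z+charge peaks are matched
to candidate fragments within a ppm tolerance; MS2 spectra are scored against
the candidate's theoretical c/y/w/a-B ion set; and the resulting records are
passed through the filter stack used for map generation: specific termini
only, unique placement, signed ppm window, minimum confidence, MS2 evidence
required, observed monoisotopic mass required.

The confidence score here is an original, documented surrogate for
proprietary search-engine scores: the mean of (i) the fraction of theoretical
singly- and doubly-charged ions matched and (ii) the fraction of observed
intensity carried by matched peaks.  It is deterministic and monotone in
matched evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .construct import MrnaConstruct
from .digest import (
    RNASE_T1,
    DEFAULT_MAX_MISSED,
    EnzymeSpec,
    TheoreticalFragment,
    UniquenessClass,
    classify_uniqueness,
    enumerate_fragments,
)
from .masses import ms2_ions, neutral_mass_from_mz, ppm_error

__all__ = [
    "Spectrum",
    "IdentificationRecord",
    "FilterConfig",
    "match_precursors",
    "score_spectrum",
    "apply_filters",
    "identify_against",
    "read_mgf",
    "write_mgf",
    "read_ms1_csv",
    "records_to_frame",
]

logger = logging.getLogger(__name__)

_H2O = 18.0105646863  # monoisotopic, cyclic vs linear 3'-phosphate offset


@dataclass
class Spectrum:
    """One centroided MS2 spectrum with its precursor."""

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int  # magnitude of the negative charge
    mz: np.ndarray
    intensity: np.ndarray

    @property
    def precursor_neutral_mass(self) -> float:
        return neutral_mass_from_mz(self.precursor_mz, self.precursor_charge)


@dataclass
class IdentificationRecord:
    """One matched oligoribonucleotide."""

    fragment: TheoreticalFragment
    observed_mass: float
    delta_ppm: float
    confidence: float = 0.0
    id_type: str = "MS1-only"  # or "MS2"
    uniqueness: UniquenessClass | None = None
    source_condition: str = ""
    ms1_area: float = 0.0
    spectrum_id: str = ""

    def __post_init__(self):
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")
        if not np.isfinite(self.delta_ppm):
            raise ValueError("delta_ppm must be finite")


@dataclass
class FilterConfig:
    """The identification filter stack.

    Defaults mirror typical oligonucleotide map-generation settings:
    specific termini only, at most one placement (unique), a +/-20 ppm
    window, confidence >= 0.90, MS2 evidence and an experimental
    monoisotopic mass required.
    """

    require_specific: bool = True
    max_nonunique_placements: int = 1
    ppm_window: float = 20.0
    min_confidence: float = 0.90
    require_ms2: bool = True
    require_observed_mass: bool = True

    def __post_init__(self):
        if self.ppm_window <= 0:
            raise ValueError("ppm_window must be > 0")
        if not (0.0 <= self.min_confidence <= 1.0):
            raise ValueError("min_confidence must lie in [0, 1]")


def _peak_neutral_masses(peaks: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Neutral mass per MS1 peak row; NaN where underivable (warned)."""
    n = len(peaks)
    neutral = np.full(n, np.nan)
    if "neutral_mass" in peaks.columns:
        neutral = peaks["neutral_mass"].to_numpy(dtype=float, copy=True)
    missing = ~np.isfinite(neutral)
    if missing.any() and "mz" in peaks.columns and "charge" in peaks.columns:
        mzv = peaks["mz"].to_numpy(dtype=float)
        chg = peaks["charge"].to_numpy(dtype=float)
        ok = missing & np.isfinite(mzv) & np.isfinite(chg) & (chg != 0)
        neutral[ok] = mzv[ok] * np.abs(chg[ok]) + np.abs(chg[ok]) * 1.00727646688
    bad = ~np.isfinite(neutral)
    if bad.any():
        logger.warning(
            "skipping %d MS1 peak(s) with neither neutral mass nor m/z+charge",
            int(bad.sum()),
        )
    return neutral, ~bad


def match_precursors(
    peaks: pd.DataFrame,
    candidates: Sequence[TheoreticalFragment],
    tol_ppm: float = 5.0,
    source_condition: str = "",
) -> list[IdentificationRecord]:
    """Match MS1 peaks to candidate fragments within ``tol_ppm``.

    ``peaks`` needs a ``neutral_mass`` column and/or ``mz`` + ``charge``
    columns, plus ``intensity``.  Every peak-candidate pair inside the
    tolerance yields one record (ambiguity is preserved and resolved only by
    the uniqueness/coverage layer).
    """
    if not candidates:
        return []
    cand_mass = np.array([c.neutral_mass for c in candidates])
    order = np.argsort(cand_mass)
    sorted_mass = cand_mass[order]

    neutral, usable = _peak_neutral_masses(peaks)
    intensity = (
        peaks["intensity"].to_numpy(dtype=float)
        if "intensity" in peaks.columns
        else np.ones(len(peaks))
    )
    records: list[IdentificationRecord] = []
    for idx in np.flatnonzero(usable):
        m = neutral[idx]
        half = m * tol_ppm * 1e-6
        lo = np.searchsorted(sorted_mass, m - half, side="left")
        hi = np.searchsorted(sorted_mass, m + half, side="right")
        for k in order[lo:hi]:
            cand = candidates[k]
            records.append(
                IdentificationRecord(
                    fragment=cand,
                    observed_mass=m,
                    delta_ppm=ppm_error(m, cand.neutral_mass),
                    ms1_area=float(intensity[idx]),
                    source_condition=source_condition,
                )
            )
    return records


def score_spectrum(
    spectrum: Spectrum,
    candidate: TheoreticalFragment,
    ms2_tol_ppm: float = 20.0,
    series: Iterable[str] = ("c", "y", "w", "a-B"),
    charges: Iterable[int] = (1, 2),
) -> float:
    """Confidence in [0, 1] for a candidate explaining an MS2 spectrum.

    0.5 x (fraction of theoretical ions matched within tolerance) +
    0.5 x (fraction of total observed intensity carried by matched peaks).
    Candidates shorter than two residues score 0.
    """
    if len(candidate.sequence) < 2:
        return 0.0
    five = candidate.cap if candidate.cap is not None else candidate.five_prime
    theo = ms2_ions(
        candidate.sequence,
        five_prime=five,
        three_prime=candidate.three_prime,
        series=series,
        charges=charges,
    )
    if not theo or len(spectrum.mz) == 0:
        return 0.0
    theo_mz = np.sort(np.array([ion.mz for ion in theo]))
    obs_mz = np.asarray(spectrum.mz, dtype=float)
    obs_int = np.asarray(spectrum.intensity, dtype=float)

    # theoretical ion matched if any observed peak within tolerance
    pos = np.searchsorted(np.sort(obs_mz), theo_mz)
    sorted_obs = np.sort(obs_mz)
    matched_theo = 0
    for t, p in zip(theo_mz, pos):
        tol = t * ms2_tol_ppm * 1e-6
        near = []
        if p < len(sorted_obs):
            near.append(sorted_obs[p])
        if p > 0:
            near.append(sorted_obs[p - 1])
        if any(abs(o - t) <= tol for o in near):
            matched_theo += 1
    frac_ions = matched_theo / len(theo_mz)

    # observed peak matched if within tolerance of any theoretical ion
    pos_o = np.searchsorted(theo_mz, obs_mz)
    matched_int = 0.0
    for o, inten, p in zip(obs_mz, obs_int, pos_o):
        tol = o * ms2_tol_ppm * 1e-6
        near = []
        if p < len(theo_mz):
            near.append(theo_mz[p])
        if p > 0:
            near.append(theo_mz[p - 1])
        if any(abs(o - t) <= tol for t in near):
            matched_int += inten
    total_int = float(obs_int.sum())
    frac_int = matched_int / total_int if total_int > 0 else 0.0
    return 0.5 * frac_ions + 0.5 * frac_int


_FILTER_ORDER = (
    "nonspecific",
    "nonunique",
    "ppm_window",
    "confidence",
    "require_ms2",
    "observed_mass",
)


def apply_filters(
    records: Sequence[IdentificationRecord],
    cfg: FilterConfig | None = None,
) -> tuple[list[IdentificationRecord], dict[str, int]]:
    """Apply the filter stack; returns (kept records, removal report).

    Order is preserved; the report counts removals per criterion (a record
    is charged to the first criterion that rejects it).  The operation is
    idempotent and monotone: enabling more criteria never enlarges the
    surviving set.
    """
    cfg = cfg or FilterConfig()
    kept: list[IdentificationRecord] = []
    report = {k: 0 for k in _FILTER_ORDER}
    for rec in records:
        u = rec.uniqueness
        if cfg.require_specific and u is not None and u.value == "nonspecific":
            report["nonspecific"] += 1
            continue
        if (
            u is not None
            and u.value != "nonspecific"
            and u.occurrence_count > cfg.max_nonunique_placements
        ):
            report["nonunique"] += 1
            continue
        if abs(rec.delta_ppm) > cfg.ppm_window:
            report["ppm_window"] += 1
            continue
        if rec.confidence < cfg.min_confidence:
            report["confidence"] += 1
            continue
        if cfg.require_ms2 and rec.id_type != "MS2":
            report["require_ms2"] += 1
            continue
        if cfg.require_observed_mass and not (rec.observed_mass > 0):
            report["observed_mass"] += 1
            continue
        kept.append(rec)
    return kept, report


def identify_against(
    construct: MrnaConstruct,
    ms1_peaks: pd.DataFrame,
    spectra: Sequence[Spectrum] = (),
    *,
    enzyme: EnzymeSpec = RNASE_T1,
    max_missed: int = DEFAULT_MAX_MISSED,
    termini: Sequence[str] = ("cyclic_phosphate", "linear_phosphate"),
    mass_cap: float | None = 30_000.0,
    tol_ppm: float = 5.0,
    ms2_tol_ppm: float = 20.0,
    filters: FilterConfig | None = None,
    source_condition: str = "",
) -> tuple[list[IdentificationRecord], dict[str, int]]:
    """Full identification pipeline against one construct.

    Enumerates candidates, matches MS1 peaks at ``tol_ppm``, scores each
    record against MS2 spectra whose precursor matches the candidate mass,
    classifies uniqueness, and applies the filter stack.  Returns the kept
    records and the filter report.
    """
    candidates = enumerate_fragments(
        construct, enzyme, max_missed=max_missed, termini=termini, mass_cap=mass_cap
    )
    records = match_precursors(
        ms1_peaks, candidates, tol_ppm=tol_ppm, source_condition=source_condition
    )

    # uniqueness, cached per (sequence, termini) signature
    cache: dict[tuple, UniquenessClass] = {}
    for rec in records:
        key = (rec.fragment.sequence, rec.fragment.three_prime)
        if key not in cache:
            cache[key] = classify_uniqueness(rec.fragment, construct, enzyme)
        rec.uniqueness = cache[key]

    if spectra:
        prec = np.array([s.precursor_neutral_mass for s in spectra])
        order = np.argsort(prec)
        sorted_prec = prec[order]
        score_cache: dict[tuple, tuple[float, str]] = {}
        for rec in records:
            m = rec.fragment.neutral_mass
            half = m * tol_ppm * 1e-6
            lo = np.searchsorted(sorted_prec, m - half, side="left")
            hi = np.searchsorted(sorted_prec, m + half, side="right")
            best, best_id = 0.0, ""
            for k in order[lo:hi]:
                sp = spectra[k]
                key = (id(sp), rec.fragment.sequence, rec.fragment.five_prime,
                       rec.fragment.three_prime)
                if key not in score_cache:
                    score_cache[key] = (
                        score_spectrum(sp, rec.fragment, ms2_tol_ppm),
                        sp.spectrum_id,
                    )
                sc, sid = score_cache[key]
                if sc > best:
                    best, best_id = sc, sid
            if best_id:
                rec.confidence = best
                rec.id_type = "MS2"
                rec.spectrum_id = best_id

    return apply_filters(records, filters)


# ---------------------------------------------------------------------------
# I/O


def read_mgf(path) -> list[Spectrum]:
    """Read centroided MS2 spectra from an MGF file (negative-mode charges)."""
    out = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            charge = params.get("charge")
            z = abs(int(charge[0])) if charge else 1
            out.append(
                Spectrum(
                    spectrum_id=str(params.get("title", f"spectrum{i}")),
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=z,
                    mz=np.asarray(entry["m/z array"], dtype=float),
                    intensity=np.asarray(entry["intensity array"], dtype=float),
                )
            )
    return out


def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    """Write MS2 spectra as MGF (charges annotated as negative)."""
    entries = [
        {
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": {
                "title": s.spectrum_id,
                "pepmass": s.precursor_mz,
                "charge": [-int(s.precursor_charge)],
            },
        }
        for s in spectra
    ]
    _mgf.write(entries, str(path), file_mode="w")


def read_ms1_csv(path) -> pd.DataFrame:
    """Read an MS1 peak table (CSV; '#' lines are comments)."""
    return pd.read_csv(path, comment="#")


def estimate_hydrolysis_fraction(
    records: Sequence[IdentificationRecord],
    paired_mass_floor: float = 470.0,
) -> tuple[float, float]:
    """Estimate the linear-phosphate share of cut 3' termini.

    Returns ``(fraction, weight)`` where fraction is the MS1-area-weighted
    share of identified linear 3'-phosphate termini among all cut termini
    (cyclic + linear; construct-end 3'-OH fragments are excluded) and
    weight is the total area behind the estimate.  Since a fragment's
    synthetic MS1 area sums to its molecule count over its charge states,
    the weight plays the role of the binomial sample size on simulated data.

    Two selection rules keep the area weighting unbiased:

    * each observed MS1 peak is counted once, and only when every candidate
      it matched carries the same 3'-terminus class — an ambiguity-preserving
      matcher otherwise hands the full peak area to several (isobaric)
      candidates at once;
    * fragments whose cyclic-form neutral mass lies below
      ``paired_mass_floor`` are excluded, since just above the negative-mode
      scan window's singly-charged cutoff only the (one-water-heavier)
      linear form of a span is detectable.
    """
    groups: dict[tuple, tuple[set, set, float]] = {}
    for r in records:
        tp = r.fragment.three_prime
        if tp == "OH":
            continue
        cyclic_form_mass = r.fragment.neutral_mass - (
            _H2O if tp == "linear_phosphate" else 0.0
        )
        if cyclic_form_mass < paired_mass_floor:
            continue
        key = (r.source_condition, r.observed_mass, r.ms1_area)
        termini, spans, area = groups.get(key, (set(), set(), r.ms1_area))
        termini.add(tp)
        spans.add(r.fragment.span)
        groups[key] = (termini, spans, area)

    # A span touched by any mixed-terminus peak is excluded with *both* its
    # terminus forms; dropping only the ambiguous form would leave its
    # counterpart over-represented.
    excluded_spans: set = set()
    for termini, spans, _ in groups.values():
        if len(termini) > 1:
            excluded_spans |= spans

    linear = cyclic = 0.0
    for termini, spans, area in groups.values():
        if len(termini) > 1 or spans & excluded_spans:
            continue
        if termini == {"linear_phosphate"}:
            linear += area
        else:
            cyclic += area
    total = linear + cyclic
    if total == 0:
        raise ValueError("no cut-terminus identifications to estimate from")
    return linear / total, total



def records_to_frame(records: Sequence[IdentificationRecord]) -> pd.DataFrame:
    """Identification table as a DataFrame with a documented column set."""
    rows = []
    for r in records:
        u = r.uniqueness
        rows.append(
            {
                "sequence": r.fragment.sequence,
                "start": r.fragment.start,
                "end": r.fragment.end,
                "five_prime": r.fragment.five_prime,
                "three_prime": r.fragment.three_prime,
                "missed_cleavages": r.fragment.missed_cleavages,
                "theoretical_mass": r.fragment.neutral_mass,
                "observed_mass": r.observed_mass,
                "delta_ppm": r.delta_ppm,
                "confidence": r.confidence,
                "id_type": r.id_type,
                "uniqueness": u.value if u else "",
                "occurrence_count": u.occurrence_count if u else 0,
                "source_condition": r.source_condition,
                "ms1_area": r.ms1_area,
            }
        )
    return pd.DataFrame(rows)
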