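"""Simulation of flow/temperature-controlled partial RNase digestion.

The kinetic model: a molecule resides in the immobilised-enzyme column for
``tau = column_volume / flow_rate`` seconds.  Each cleavable site i is cut
independently with probability ``p_i = 1 - exp(-k_i * tau)`` where
``k_i = k_ref * q10^((T - 25)/10) * a_i`` and the per-site accessibility
``a_i`` is lognormal — modelling the site-to-site heterogeneity expected from
RNA secondary structure (accessible, unpaired guanosines digest faster).
Raising the temperature or lowering the flow rate therefore shifts the
digest toward shorter fragments with fewer missed cleavages, reproducing the
qualitative behaviour of a tunable online partial digest.

A cut 3' terminus is the 2',3'-cyclic phosphate unless hydrolysed to the
3'-linear phosphate, with probability ``hydrolysis_fraction``.

The module also emits synthetic MS1 peak lists (negative-mode charge
envelopes in the instrument's 450-3000 m/z window, ppm-scale mass noise) and
MS2 spectra, so the whole downstream pipeline is testable without
instrument data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .construct import MrnaConstruct
from .digest import RNASE_T1, EnzymeSpec, TheoreticalFragment, cleavage_sites
from .identify import Spectrum, write_mgf
from .masses import fragment_mass, ms2_ions, mz as _mz

__all__ = [
    "DigestConditions",
    "SimulatedDigest",
    "random_construct",
    "site_cut_probabilities",
    "simulate_digest",
    "generate_ms_data",
    "mean_fragment_length",
    "simulate_five_prime_species",
    "simulate_polyA_ladder",
]

MZ_WINDOW = (450.0, 3000.0)


@dataclass(frozen=True)
class DigestConditions:
    """Operating point of the online digestion column.

    Defaults describe a mid-partial digest: 25 degC, 50 uL/min through a
    70 uL column bed (residence time 84 s), base cleavage rate 0.008 per
    second with a Q10 of 2, lognormal accessibility spread sigma = 1, and a
    16% chance that a cut terminus is hydrolysed to the linear 3'-phosphate.
    """

    temperature_C: float = 25.0
    flow_rate: float = 50.0  # uL/min
    column_volume: float = 70.0  # uL
    k_ref: float = 0.008  # 1/s at 25 degC for unit accessibility
    q10: float = 2.0
    accessibility_sigma: float = 1.0
    hydrolysis_fraction: float = 0.16
    seed: int = 0

    def __post_init__(self):
        if self.flow_rate <= 0:
            raise ValueError("flow_rate must be > 0")
        if not (0.0 <= self.hydrolysis_fraction <= 1.0):
            raise ValueError("hydrolysis_fraction must lie in [0, 1]")
        if self.q10 <= 0:
            raise ValueError("q10 must be > 0")

    @property
    def residence_time_s(self) -> float:
        """Residence time in the enzyme column, seconds."""
        return self.column_volume / self.flow_rate * 60.0


@dataclass
class SimulatedDigest:
    """Fragment abundances produced by one simulated digest."""

    construct: MrnaConstruct
    conditions: DigestConditions
    site_probabilities: np.ndarray
    fragments: list[tuple[TheoreticalFragment, float]]
    n_molecules: int
    mode: str  # "expectation" | "sample"

    def total_abundance(self) -> float:
        return sum(a for _, a in self.fragments)


def random_construct(
    length: int = 930,
    seed: int = 0,
    polyA_length: int = 70,
    name: str = "synthetic-mrna",
    gc: float = 0.5,
) -> MrnaConstruct:
    """A random mRNA-like fixture: random body plus a 3' poly(A) tail.

    The default emulates a ~930 nt reporter-sized construct carrying a
    70 nt tail; the body is i.i.d. with the requested GC fraction.
    """
    if not (0 < polyA_length < length):
        raise ValueError("polyA_length must lie in (0, length)")
    rng = np.random.default_rng(seed)
    body_len = length - polyA_length
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    body = "".join(rng.choice(list("ACGU"), size=body_len, p=p))
    sequence = body + "A" * polyA_length
    return MrnaConstruct(
        name=name,
        sequence=sequence,
        polyA_segments=[(body_len + 1, length)],
    )


def site_cut_probabilities(
    construct: MrnaConstruct,
    cond: DigestConditions,
    enzyme: EnzymeSpec = RNASE_T1,
) -> np.ndarray:
    """Per-site cut probabilities under first-order kinetics.

    The accessibility draw depends only on ``cond.seed`` and the number of
    sites, so digests of the same construct simulated at different
    temperatures or flow rates (same seed) share their site accessibility,
    as they would on a real molecule.
    """
    sites = cleavage_sites(construct.modified_sequence, enzyme)
    if not sites:
        return np.zeros(0)
    rng = np.random.default_rng(cond.seed)
    accessibility = rng.lognormal(mean=0.0, sigma=cond.accessibility_sigma,
                                  size=len(sites))
    k = cond.k_ref * cond.q10 ** ((cond.temperature_C - 25.0) / 10.0) * accessibility
    return 1.0 - np.exp(-k * cond.residence_time_s)


def _expected_fragments(
    construct: MrnaConstruct,
    cond: DigestConditions,
    p: np.ndarray,
    sites: list[int],
    n_molecules: int,
    abundance_floor: float,
) -> dict[tuple[int, int], float]:
    """Expected molecule count per span under independent-site cutting."""
    L = construct.length
    boundaries = [0] + sites + [L]
    nb = len(boundaries)
    # p_bound[i]: probability that boundary i is "open" (cut or molecule end)
    p_bound = np.concatenate([[1.0], p, [1.0]])
    out: dict[tuple[int, int], float] = {}
    for i in range(nb - 1):
        left = p_bound[i]
        interior = 1.0
        for j in range(i + 1, nb):
            abundance = n_molecules * left * interior * p_bound[j]
            if abundance >= abundance_floor:
                out[(boundaries[i] + 1, boundaries[j])] = abundance
            # extend: boundary j becomes interior (survives uncut)
            interior *= 1.0 - p_bound[j]
            if n_molecules * left * interior < abundance_floor:
                break
    return out


def _sampled_fragments(
    construct: MrnaConstruct,
    p: np.ndarray,
    sites: list[int],
    n_molecules: int,
    rng: np.random.Generator,
) -> dict[tuple[int, int], float]:
    """Monte-Carlo per-molecule cutting."""
    L = construct.length
    bounds = np.array([0] + sites + [L])
    counts: dict[tuple[int, int], float] = {}
    for _ in range(n_molecules):
        cut = np.concatenate([[True], rng.random(len(p)) < p, [True]])
        open_bounds = bounds[cut]
        for a, b in zip(open_bounds[:-1], open_bounds[1:]):
            span = (int(a) + 1, int(b))
            counts[span] = counts.get(span, 0.0) + 1.0
    return counts


def simulate_digest(
    construct: MrnaConstruct,
    cond: DigestConditions,
    n_molecules: int = 10_000,
    mode: str = "expectation",
    rel_abundance_floor: float = 1e-4,
    enzyme: EnzymeSpec = RNASE_T1,
) -> SimulatedDigest:
    """Simulate one partial digest.

    In ``expectation`` mode (deterministic, the default for tests) the
    abundance of the fragment between open boundaries is
    ``n x p(left) x p(right) x prod(1 - p(interior))``, with construct ends
    always open.  ``sample`` mode draws per-molecule cut patterns instead.
    Spans below ``rel_abundance_floor x n_molecules`` expected molecules are
    dropped.

    Each cut 3' terminus is linear phosphate with probability
    ``hydrolysis_fraction``, else cyclic: in expectation mode the abundance
    is split exactly, in sample mode binomially (seeded).
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    seq = construct.modified_sequence
    sites = cleavage_sites(seq, enzyme)
    p = site_cut_probabilities(construct, cond, enzyme)
    floor = rel_abundance_floor * n_molecules
    rng = np.random.default_rng(cond.seed + 1)

    if mode == "expectation":
        spans = _expected_fragments(construct, cond, p, sites, n_molecules, floor)
    elif mode == "sample":
        spans = _sampled_fragments(construct, p, sites, n_molecules, rng)
        spans = {s: a for s, a in spans.items() if a >= floor}
    else:
        raise ValueError(f"unknown mode {mode!r}")

    native5 = construct.five_prime_native
    native5_label = native5 if isinstance(native5, str) else native5.label
    native5_obj = None if isinstance(native5, str) else native5
    L = construct.length
    h = cond.hydrolysis_fraction

    fragments: list[tuple[TheoreticalFragment, float]] = []

    def _mk(start, end, three, abundance):
        frag_seq = seq[start - 1 : end]
        if start == 1:
            fp_label, fp = native5_label, (native5_obj or native5_label)
        else:
            fp_label, fp = "OH", "OH"
        missed = sum(1 for s in sites if start <= s < end)
        frag = TheoreticalFragment(
            start=start,
            end=end,
            sequence=frag_seq,
            five_prime=fp_label,
            three_prime=three,
            missed_cleavages=missed,
            neutral_mass=fragment_mass(frag_seq, fp, three),
            cap=native5_obj if start == 1 else None,
        )
        fragments.append((frag, abundance))

    for (start, end), abundance in sorted(spans.items()):
        if end == L:
            _mk(start, end, "OH", abundance)
        elif mode == "expectation":
            if h > 0:
                _mk(start, end, "linear_phosphate", abundance * h)
            if h < 1:
                _mk(start, end, "cyclic_phosphate", abundance * (1 - h))
        else:
            n_linear = rng.binomial(int(round(abundance)), h)
            n_cyclic = int(round(abundance)) - n_linear
            if n_linear:
                _mk(start, end, "linear_phosphate", float(n_linear))
            if n_cyclic:
                _mk(start, end, "cyclic_phosphate", float(n_cyclic))

    return SimulatedDigest(
        construct=construct,
        conditions=cond,
        site_probabilities=p,
        fragments=fragments,
        n_molecules=n_molecules,
        mode=mode,
    )


def mean_fragment_length(dig: SimulatedDigest) -> float:
    """Abundance-weighted mean fragment length (nt)."""
    total = dig.total_abundance()
    if total == 0:
        return 0.0
    return sum(len(f) * a for f, a in dig.fragments) / total


def _charge_states(neutral_mass: float, max_states: int = 3) -> list[tuple[int, float]]:
    """Charge states placing m/z inside the scan window, with weights.

    Picks up to ``max_states`` consecutive charges around the state closest
    to m/z ~ 900, weighted 0.5/0.3/0.2 — a crude but deterministic stand-in
    for a negative-mode charge envelope.
    """
    lo, hi = MZ_WINDOW
    zmin = int(np.ceil(neutral_mass / (hi + 1.0)))
    zmax = int(np.floor(neutral_mass / (lo + 1.0)))
    zmin = max(zmin, 1)
    states = [z for z in range(zmin, zmax + 1) if lo <= _mz(neutral_mass, z) <= hi]
    if not states:
        return []
    target = max(1, round(neutral_mass / 900.0))
    states.sort(key=lambda z: (abs(z - target), z))
    chosen = sorted(states[:max_states])
    weights = [0.5, 0.3, 0.2][: len(chosen)]
    wsum = sum(weights)
    return [(z, w / wsum) for z, w in zip(chosen, weights)]


def generate_ms_data(
    dig: SimulatedDigest,
    noise_ppm: float = 2.0,
    seed: int = 0,
    ms2_top_n: int = 1000,
    mass_cap: float | None = 30_000.0,
    out_ms1=None,
    out_ms2=None,
) -> tuple[pd.DataFrame, list[Spectrum]]:
    """Emit synthetic MS1 peaks and MS2 spectra for a simulated digest.

    For each fragment (below the processing mass cap), charge states with
    m/z inside the 450-3000 window are emitted with Gaussian ppm noise on
    m/z and intensity proportional to abundance.  MS2 spectra (c/y/w/a-B
    ions at charge 1-2, near-uniform intensities with jitter, same ppm
    noise) are produced for the ``ms2_top_n`` most abundant precursors.
    Deterministic per seed.  MS1 is returned as a DataFrame (written as CSV
    if ``out_ms1`` is given); MS2 as Spectrum objects (MGF if ``out_ms2``).
    """
    rng = np.random.default_rng(seed)
    rows = []
    eligible: list[tuple[TheoreticalFragment, float]] = []
    for frag, abundance in dig.fragments:
        if mass_cap is not None and frag.neutral_mass > mass_cap:
            continue
        states = _charge_states(frag.neutral_mass)
        if not states:
            continue
        eligible.append((frag, abundance))
        for z, w in states:
            true_mz = _mz(frag.neutral_mass, z)
            obs_mz = true_mz * (1.0 + rng.normal(0.0, noise_ppm) * 1e-6)
            rows.append(
                {
                    "mz": obs_mz,
                    "charge": z,
                    "neutral_mass": obs_mz * z + z * 1.00727646688,
                    "intensity": abundance * w,
                }
            )
    ms1 = pd.DataFrame(rows, columns=["mz", "charge", "neutral_mass", "intensity"])

    eligible.sort(key=lambda t: -t[1])
    spectra: list[Spectrum] = []
    for i, (frag, abundance) in enumerate(eligible[:ms2_top_n]):
        if len(frag.sequence) < 2:
            continue
        five = frag.cap if frag.cap is not None else frag.five_prime
        ions = ms2_ions(frag.sequence, five, frag.three_prime)
        if not ions:
            continue
        ion_mz = np.array([ion.mz for ion in ions])
        ion_mz = ion_mz * (1.0 + rng.normal(0.0, noise_ppm, len(ion_mz)) * 1e-6)
        intensity = 1.0 + 0.3 * rng.uniform(-1.0, 1.0, len(ion_mz))
        order = np.argsort(ion_mz)
        states = _charge_states(frag.neutral_mass)
        z0 = states[0][0]
        spectra.append(
            Spectrum(
                spectrum_id=f"sim-{dig.conditions.temperature_C:g}C-"
                f"{dig.conditions.flow_rate:g}uLmin-{i}",
                precursor_mz=_mz(frag.neutral_mass, z0)
                * (1.0 + rng.normal(0.0, noise_ppm) * 1e-6),
                precursor_charge=z0,
                mz=ion_mz[order],
                intensity=intensity[order],
            )
        )

    if out_ms1 is not None:
        ms1.to_csv(out_ms1, index=False)
    if out_ms2 is not None:
        write_mgf(spectra, out_ms2)
    return ms1, spectra


def simulate_five_prime_species(
    capping_efficiency: float = 0.863,
    total_area: float = 1e6,
    uncapped_split: Sequence[float] = (0.7, 0.2, 0.1),
    noise_rel: float = 0.0,
    seed: int = 0,
):
    """Synthetic 5'-terminal species table for cap-efficiency analysis.

    The capped share defaults to 86.3%; the uncapped remainder is split
    over triphosphate/diphosphate/monophosphate 5' ends.  Optional relative
    lognormal noise perturbs each area (seeded).
    """
    from .mam import FivePrimeSpecies  # local import avoids a cycle

    if not (0.0 <= capping_efficiency <= 1.0):
        raise ValueError("capping_efficiency must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    split = np.asarray(uncapped_split, dtype=float)
    split = split / split.sum()
    areas = {
        "Cap1-AG": capping_efficiency * total_area,
        "pppGp": (1 - capping_efficiency) * split[0] * total_area,
        "ppGp": (1 - capping_efficiency) * split[1] * total_area,
        "pGp": (1 - capping_efficiency) * split[2] * total_area,
    }
    out = []
    for label, area in areas.items():
        if noise_rel > 0:
            area *= rng.lognormal(0.0, noise_rel)
        out.append(
            FivePrimeSpecies(
                label=label,
                theoretical_mass=0.0,
                area=area,
                capped=(label == "Cap1-AG"),
            )
        )
    return out


def simulate_polyA_ladder(
    mean_length: float = 71.8,
    sd: float = 1.5,
    n_molecules: int = 10_000,
    base_mass: float = 18.0105646863,
    mass_noise_da: float = 0.02,
    seed: int = 0,
) -> tuple[list[tuple[float, float]], int]:
    """Synthetic deconvoluted poly(A) mass ladder.

    Samples integer tail lengths from a rounded Gaussian, builds one
    deconvoluted neutral-mass peak per observed length (mass = base +
    n x AMP residue, small Da-scale noise) with intensity equal to the
    molecule count.  Returns (peaks, true modal length of the sample).
    """
    from .mam import A_RESIDUE_MASS

    rng = np.random.default_rng(seed)
    lengths = np.rint(rng.normal(mean_length, sd, n_molecules)).astype(int)
    lengths = lengths[lengths >= 0]
    values, counts = np.unique(lengths, return_counts=True)
    true_mode = int(values[np.argmax(counts)])
    peaks = []
    for n, c in zip(values, counts):
        mass = base_mass + n * A_RESIDUE_MASS + rng.normal(0.0, mass_noise_da)
        peaks.append((float(mass), float(c)))
    return peaks, true_mode
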