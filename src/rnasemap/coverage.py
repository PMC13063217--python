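"""Sequence-coverage computation, digest merging, decoy controls and maps.

Coverage counts only *unique* identified oligoribonucleotides, and the
percentage denominator excludes the annotated poly(A) tail.  Digests run at
different conditions (temperature, flow rate) can be merged with per-source
provenance, which drives the linear and spiral map colouring: one colour per
source, red for positions covered by more than one source, gray for no
coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.collections import LineCollection
from matplotlib.patches import Patch

from .construct import MrnaConstruct, make_decoy
from .identify import IdentificationRecord, identify_against

__all__ = [
    "CoverageResult",
    "DecoyControlResult",
    "compute_coverage",
    "merge_digests",
    "decoy_coverage_control",
    "render_map",
]

#: Default per-source palette (first three follow the yellow/green/blue
#: convention of combined-digest maps), with red reserved for overlap and
#: gray for no coverage.
SOURCE_COLORS = [
    "#e6c700",  # yellow
    "#3cb371",  # green
    "#4682b4",  # blue
    "#9467bd",
    "#8c564b",
    "#17becf",
]
OVERLAP_COLOR = "#d62728"
NOCOVER_COLOR = "#bfbfbf"


@dataclass
class CoverageResult:
    """Per-position coverage with provenance.

    ``covered[i]`` refers to position i+1 (1-based coordinates elsewhere).
    ``percent`` is computed over effective (non-poly(A)) positions only.
    """

    covered: np.ndarray
    percent: float
    contributing_ids: list[IdentificationRecord]
    per_source_masks: dict[str, np.ndarray]
    uncovered_intervals: list[tuple[int, int]]
    construct: MrnaConstruct | None = None

    @property
    def overlap_mask(self) -> np.ndarray:
        """Positions covered by two or more sources."""
        counts = np.zeros(len(self.covered), dtype=int)
        for mask in self.per_source_masks.values():
            counts += mask.astype(int)
        return counts >= 2


def _mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    """1-based inclusive intervals of True runs."""
    intervals = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return intervals
    start = prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            intervals.append((int(start) + 1, int(prev) + 1))
            start = i
        prev = i
    intervals.append((int(start) + 1, int(prev) + 1))
    return intervals


def _coverage_from_masks(
    construct: MrnaConstruct,
    per_source: dict[str, np.ndarray],
    contributing: list[IdentificationRecord],
) -> CoverageResult:
    L = construct.length
    covered = np.zeros(L, dtype=bool)
    for mask in per_source.values():
        covered |= mask
    effective = ~construct.polyA_mask()
    n_eff = int(effective.sum())
    percent = 100.0 * int((covered & effective).sum()) / n_eff if n_eff else 0.0
    uncovered = _mask_to_intervals(effective & ~covered)
    return CoverageResult(
        covered=covered,
        percent=percent,
        contributing_ids=contributing,
        per_source_masks=per_source,
        uncovered_intervals=uncovered,
        construct=construct,
    )


def compute_coverage(
    records: Sequence[IdentificationRecord],
    construct: MrnaConstruct,
    source: str | None = None,
) -> CoverageResult:
    """Unique-fragment sequence coverage of one digest.

    Only records classified *unique* contribute; every position of a
    contributing record's span is marked.  Percent coverage is over
    effective (non-poly(A)) positions; uncovered intervals are reported in
    ascending order over the effective region.
    """
    L = construct.length
    mask = np.zeros(L, dtype=bool)
    contributing = []
    for rec in records:
        f = rec.fragment
        if not (1 <= f.start <= f.end <= L):
            raise ValueError(f"record span {f.span} outside construct 1..{L}")
        if rec.uniqueness is None or rec.uniqueness.value != "unique":
            continue
        mask[f.start - 1 : f.end] = True
        contributing.append(rec)
    label = source if source is not None else (
        contributing[0].source_condition if contributing else ""
    )
    return _coverage_from_masks(construct, {label or "all": mask}, contributing)


def merge_digests(
    per_condition: Mapping[str, Sequence[IdentificationRecord]],
    construct: MrnaConstruct,
) -> CoverageResult:
    """Union coverage over several digests with per-source provenance.

    The union of the per-source masks equals the merged mask, so merged
    percent is always >= each individual percent; positions covered by
    more than one source are exposed via :attr:`CoverageResult.overlap_mask`
    (the map's overlap colour).
    """
    if not per_condition:
        raise ValueError("at least one condition required")
    per_source: dict[str, np.ndarray] = {}
    contributing: list[IdentificationRecord] = []
    for label, records in per_condition.items():
        single = compute_coverage(records, construct, source=label)
        per_source[label] = single.covered
        contributing.extend(single.contributing_ids)
    return _coverage_from_masks(construct, per_source, contributing)


@dataclass
class DecoyControlResult:
    """Coverage obtained against composition-matched decoy sequences."""

    percents: list[float]
    seeds: list[int]

    @property
    def max_percent(self) -> float:
        return max(self.percents) if self.percents else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"decoy_seed": self.seeds, "percent": self.percents})


def decoy_coverage_control(
    construct: MrnaConstruct,
    ms1_peaks: pd.DataFrame,
    spectra=(),
    n_decoys: int = 5,
    seed: int = 0,
    **identify_kwargs,
) -> DecoyControlResult:
    """Specificity control: re-run the full pipeline against decoys.

    Each decoy is a fresh composition-preserving shuffle of the construct
    (seeded from ``seed``) which is re-digested in silico — candidate
    generation, matching, scoring and filtering all run against the decoy
    sequence, exactly as for the target.  Deterministic per seed.
    """
    if n_decoys < 1:
        raise ValueError("n_decoys must be >= 1")
    percents, seeds = [], []
    for k in range(n_decoys):
        decoy_seed = seed + k
        decoy = make_decoy(construct, decoy_seed)
        records, _ = identify_against(decoy, ms1_peaks, spectra, **identify_kwargs)
        result = compute_coverage(records, decoy)
        percents.append(result.percent)
        seeds.append(decoy_seed)
    return DecoyControlResult(percents=percents, seeds=seeds)


# ---------------------------------------------------------------------------
# Rendering


def _source_color_table(sources: Sequence[str]) -> dict[str, str]:
    return {s: SOURCE_COLORS[i % len(SOURCE_COLORS)] for i, s in enumerate(sources)}


def _pack_lanes(spans: list[tuple[int, int]]) -> list[int]:
    """Greedy interval lane assignment; overlapping spans get distinct lanes."""
    lane_ends: list[int] = []
    lanes = []
    for start, end in spans:
        for lane, busy_until in enumerate(lane_ends):
            if start > busy_until:
                lane_ends[lane] = end
                lanes.append(lane)
                break
        else:
            lane_ends.append(end)
            lanes.append(len(lane_ends) - 1)
    return lanes


def _legend(ax, colors: dict[str, str]) -> None:
    handles = [Patch(facecolor=c, label=s) for s, c in colors.items()]
    handles.append(Patch(facecolor=OVERLAP_COLOR, label="overlap"))
    handles.append(Patch(facecolor=NOCOVER_COLOR, label="no coverage"))
    ax.legend(handles=handles, loc="upper right", fontsize=7, frameon=False)


def _position_colors(result: CoverageResult) -> list[str]:
    L = len(result.covered)
    colors = [NOCOVER_COLOR] * L
    table = _source_color_table(list(result.per_source_masks))
    counts = np.zeros(L, dtype=int)
    for mask in result.per_source_masks.values():
        counts += mask.astype(int)
    for label, mask in result.per_source_masks.items():
        c = table[label]
        for i in np.flatnonzero(mask & (counts == 1)):
            colors[i] = c
    for i in np.flatnonzero(counts >= 2):
        colors[i] = OVERLAP_COLOR
    return colors


def render_map(
    result: CoverageResult,
    style: str = "linear",
    out: str = "map.svg",
    title: str | None = None,
) -> str:
    """Render a coverage result as a vector-graphics sequence map.

    ``linear`` draws stacked fragment bars over a position axis (lane-packed
    so same-span fragments never overplot) above a per-position coverage
    track.  ``spiral`` draws the sequence as an Archimedean spiral coloured
    per source, red where sources overlap and gray where nothing covers.
    Layout is deterministic for a given result.
    """
    plt.rcParams["svg.hashsalt"] = "rnasemap"
    L = len(result.covered)
    table = _source_color_table(list(result.per_source_masks))

    if style == "linear":
        fig, (ax_frag, ax_cov) = plt.subplots(
            2, 1, figsize=(10, 4.5), height_ratios=[4, 1], sharex=True
        )
        frags = sorted(
            result.contributing_ids, key=lambda r: (r.fragment.start, r.fragment.end)
        )
        spans = [(r.fragment.start, r.fragment.end) for r in frags]
        lanes = _pack_lanes(spans)
        for rec, lane in zip(frags, lanes):
            f = rec.fragment
            color = table.get(rec.source_condition, SOURCE_COLORS[0])
            ax_frag.broken_barh(
                [(f.start - 0.5, f.end - f.start + 1)], (lane, 0.8), facecolor=color
            )
        ax_frag.set_ylabel("fragments")
        ax_frag.set_ylim(-0.5, (max(lanes) if lanes else 0) + 1.5)
        _legend(ax_frag, table)

        pos_colors = _position_colors(result)
        ax_cov.bar(
            np.arange(1, L + 1), np.ones(L), width=1.0, color=pos_colors, linewidth=0
        )
        ax_cov.set_yticks([])
        ax_cov.set_xlim(0.5, L + 0.5)
        ax_cov.set_xlabel("position (nt)")
        ax_cov.set_ylabel("coverage")
    elif style == "spiral":
        fig, ax = plt.subplots(figsize=(6, 6))
        turns = max(4.0, round(np.sqrt(L) / 4.0))
        theta = np.linspace(0, turns * 2 * np.pi, L + 1)
        # Archimedean spiral scaled to fill the unit square
        r0, r1 = 0.15, 1.0
        r = r0 + (r1 - r0) * theta / theta[-1]
        x, y = r * np.cos(theta), r * np.sin(theta)
        pts = np.column_stack([x, y])
        segments = np.stack([pts[:-1], pts[1:]], axis=1)
        lc = LineCollection(
            segments, colors=_position_colors(result), linewidths=3.0
        )
        ax.add_collection(lc)
        ax.set_xlim(-1.1, 1.1)
        ax.set_ylim(-1.1, 1.1)
        ax.set_aspect("equal")
        ax.axis("off")
        _legend(ax, table)
    else:
        raise ValueError(f"unknown map style {style!r}")

    if title is None and result.construct is not None:
        title = f"{result.construct.name}: {result.percent:.1f}% coverage"
    if title:
        fig.suptitle(title, fontsize=10)
    fig.savefig(out)
    plt.close(fig)
    return str(out)
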