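"""Run configuration, the end-to-end pipeline, and identification-table I/O.

A single YAML configuration drives a full run: construct annotation, enzyme,
digestion/simulation parameters, tolerances, the filter stack, decoy
controls and the multi-attribute monitoring inputs.  Every table written
carries a header comment with the tool version, a configuration hash and the
seed, so summary numbers are recomputable from the intermediate CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .construct import MrnaConstruct, read_mrna_construct
from .coverage import (
    compute_coverage,
    decoy_coverage_control,
    merge_digests,
    render_map,
)
from .digest import (
    ENZYMES,
    RNASE_T1,
    TheoreticalFragment,
    classify_uniqueness,
    enumerate_fragments,
    fragments_to_frame,
    locate_occurrences,
)
from .identify import (
    FilterConfig,
    IdentificationRecord,
    identify_against,
    records_to_frame,
)
from .mam import cap_efficiency, polyA_distribution, species_table_from_frame
from .masses import fragment_mass
from .simulate import (
    DigestConditions,
    generate_ms_data,
    simulate_digest,
    simulate_five_prime_species,
    simulate_polyA_ladder,
)

__all__ = ["RunConfig", "load_run_config", "run_pipeline", "import_id_table",
           "export_id_table", "DEFAULT_COLUMN_ALIASES"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    fasta: str
    output_dir: str = "rnasemap-out"
    seed: int = 0
    annotation: dict = field(default_factory=dict)
    enzyme: str = "T1"
    max_missed: int = 8
    termini: tuple[str, ...] = ("cyclic_phosphate", "linear_phosphate")
    mass_cap: float = 30_000.0
    conditions: list[dict] = field(default_factory=lambda: [
        {"label": "5C", "temperature_C": 5.0, "flow_rate": 50.0},
        {"label": "25C", "temperature_C": 25.0, "flow_rate": 50.0},
        {"label": "45C", "temperature_C": 45.0, "flow_rate": 50.0},
    ])
    n_molecules: int = 10_000
    noise_ppm: float = 2.0
    ms2_top_n: int = 1000
    ms1_tol_ppm: float = 5.0
    ms2_tol_ppm: float = 20.0
    filters: dict = field(default_factory=dict)
    n_decoys: int = 2
    mam: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_run_config(path) -> RunConfig:
    """Load a RunConfig from a YAML file; missing files are an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in RunConfig.__dataclass_fields__})
    if not Path(cfg.fasta).exists():
        raise FileNotFoundError(f"FASTA not found: {cfg.fasta}")
    cfg.termini = tuple(cfg.termini)
    return cfg


def _header(cfg: RunConfig) -> str:
    return (
        f"# rnasemap {__version__} seed={cfg.seed} "
        f"config_hash={cfg.config_hash()}\n"
    )


def _write_csv(frame: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        frame.to_csv(fh, index=False)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute digest -> simulate -> identify -> filter -> coverage -> maps -> MAM.

    Returns the machine-readable summary (also written to summary.json):
    percent coverage per condition and merged, counts removed per filter,
    decoy max coverage, cap efficiency and poly(A) modal length.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    construct = read_mrna_construct(cfg.fasta, cfg.annotation or None)
    enzyme = ENZYMES.get(cfg.enzyme, RNASE_T1)
    filters = FilterConfig(**cfg.filters) if cfg.filters else FilterConfig()

    fragments = enumerate_fragments(
        construct, enzyme, cfg.max_missed, cfg.termini, cfg.mass_cap
    )
    _write_csv(fragments_to_frame(fragments), out / "fragments.csv", cfg)

    per_condition: dict[str, list[IdentificationRecord]] = {}
    filter_counts: dict[str, dict[str, int]] = {}
    all_peaks = None
    all_spectra: list = []
    for spec_dict in cfg.conditions:
        label = str(spec_dict.get("label") or f"{spec_dict['temperature_C']:g}C")
        cond = DigestConditions(
            **{k: v for k, v in spec_dict.items() if k != "label"},
            seed=cfg.seed,
        )
        dig = simulate_digest(construct, cond, cfg.n_molecules)
        peaks, spectra = generate_ms_data(
            dig, cfg.noise_ppm, seed=cfg.seed, ms2_top_n=cfg.ms2_top_n,
            mass_cap=cfg.mass_cap,
            out_ms1=out / f"ms1_{label}.csv", out_ms2=out / f"ms2_{label}.mgf",
        )
        records, report = identify_against(
            construct, peaks, spectra,
            enzyme=enzyme, max_missed=cfg.max_missed, termini=cfg.termini,
            mass_cap=cfg.mass_cap, tol_ppm=cfg.ms1_tol_ppm,
            ms2_tol_ppm=cfg.ms2_tol_ppm, filters=filters,
            source_condition=label,
        )
        per_condition[label] = records
        filter_counts[label] = report
        all_peaks = peaks if all_peaks is None else pd.concat(
            [all_peaks, peaks], ignore_index=True
        )
        all_spectra.extend(spectra)

    all_records = [r for recs in per_condition.values() for r in recs]
    _write_csv(records_to_frame(all_records), out / "identifications.csv", cfg)

    merged = merge_digests(per_condition, construct)
    coverage_rows = [
        {"condition": label,
         "percent": compute_coverage(recs, construct, source=label).percent,
         "n_unique_ids": sum(
             1 for r in recs if r.uniqueness and r.uniqueness.value == "unique")}
        for label, recs in per_condition.items()
    ]
    coverage_rows.append(
        {"condition": "merged", "percent": merged.percent,
         "n_unique_ids": len(merged.contributing_ids)}
    )
    _write_csv(pd.DataFrame(coverage_rows), out / "coverage.csv", cfg)

    render_map(merged, "linear", out / "map_linear.svg")
    render_map(merged, "spiral", out / "map_spiral.svg")

    decoys = decoy_coverage_control(
        construct, all_peaks, all_spectra, n_decoys=cfg.n_decoys, seed=cfg.seed,
        enzyme=enzyme, max_missed=cfg.max_missed, termini=cfg.termini,
        mass_cap=cfg.mass_cap, tol_ppm=cfg.ms1_tol_ppm,
        ms2_tol_ppm=cfg.ms2_tol_ppm, filters=filters,
    )
    _write_csv(decoys.to_frame(), out / "decoy_coverage.csv", cfg)

    mam_cfg = cfg.mam or {}
    if "species_table" in mam_cfg:
        species = species_table_from_frame(
            pd.read_csv(mam_cfg["species_table"], comment="#"))
    else:
        species = simulate_five_prime_species(
            capping_efficiency=mam_cfg.get("capping_efficiency", 0.863),
            seed=cfg.seed,
        )
    cap_pct = cap_efficiency(species)

    if "polya_table" in mam_cfg:
        ladder = pd.read_csv(mam_cfg["polya_table"], comment="#")
        peaks = list(zip(ladder["neutral_mass"], ladder["intensity"]))
        base_mass = float(mam_cfg.get("polya_base_mass", 18.0105646863))
    else:
        peaks, _ = simulate_polyA_ladder(
            mean_length=mam_cfg.get("polya_mean", 71.8),
            sd=mam_cfg.get("polya_sd", 1.5),
            seed=cfg.seed,
        )
        base_mass = 18.0105646863
    dist = polyA_distribution(peaks, base_mass)
    _write_csv(dist.to_frame(), out / "polya_distribution.csv", cfg)

    summary = {
        "tool": "rnasemap",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "coverage_percent": {row["condition"]: row["percent"] for row in coverage_rows},
        "filter_counts": filter_counts,
        "decoy_max_coverage_percent": decoys.max_percent,
        "cap_efficiency_percent": cap_pct,
        "polya_modal_length_nt": dist.modal_length,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


# ---------------------------------------------------------------------------
# Reanalysis of exported identification tables

#: Alias map absorbing exported search-engine column layouts.  Keys are the
#: package's canonical column names; values are accepted spellings.
DEFAULT_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "sequence": ("sequence", "Sequence", "Oligonucleotide", "oligo_sequence"),
    "start": ("start", "Start", "Position Start", "start_position"),
    "end": ("end", "End", "Position End", "end_position"),
    "modifications": ("modifications", "Mod", "Modifications", "mod_text"),
    "delta_ppm": ("delta_ppm", "Δppm", "dppm", "Delta ppm", "ppm"),
    "confidence": ("confidence", "Conf. Score", "Confidence Score", "conf_score"),
    "id_type": ("id_type", "ID Type"),
    "observed_mass": ("observed_mass", "Mono Mass Exp.", "Monoisotopic Mass Exp"),
    "ms1_area": ("ms1_area", "Area", "MS Area", "area"),
    "source_condition": ("source_condition", "source", "Condition", "Sample"),
}


def _resolve_columns(frame: pd.DataFrame, aliases) -> dict[str, str]:
    found = {}
    for canonical, spellings in aliases.items():
        for s in spellings:
            if s in frame.columns:
                found[canonical] = s
                break
    return found


def _termini_from_mod_text(text: str) -> str:
    low = str(text).lower()
    if "cyclic" in low:
        return "cyclic_phosphate"
    if "phosphate" in low or "3'p" in low or "3p" in low:
        return "linear_phosphate"
    return "OH"


def import_id_table(
    path,
    column_aliases: dict | None = None,
    construct: MrnaConstruct | None = None,
    enzyme=RNASE_T1,
    source_condition: str = "",
) -> tuple[list[IdentificationRecord], pd.DataFrame]:
    """Import an exported identification table (CSV) for reanalysis.

    The alias map absorbs foreign column spellings; ``sequence`` is
    mandatory, everything else optional.  When a construct is given,
    missing positions are recomputed by substring placement and uniqueness
    is (re)classified; rows whose sequence cannot be placed are returned in
    the second element and excluded from the records.
    """
    aliases = dict(DEFAULT_COLUMN_ALIASES)
    if column_aliases:
        for k, v in column_aliases.items():
            aliases[k] = tuple(v) if not isinstance(v, str) else (v,)
    frame = pd.read_csv(path, comment="#")
    cols = _resolve_columns(frame, aliases)
    if "sequence" not in cols:
        raise ValueError(
            "mandatory column missing: sequence "
            f"(accepted spellings: {aliases['sequence']})"
        )

    records: list[IdentificationRecord] = []
    unmapped_rows = []
    target = construct.modified_sequence if construct is not None else None
    for _, row in frame.iterrows():
        seq = str(row[cols["sequence"]]).strip()
        start = int(row[cols["start"]]) if "start" in cols and pd.notna(row[cols["start"]]) else None
        end = int(row[cols["end"]]) if "end" in cols and pd.notna(row[cols["end"]]) else None
        if (start is None or end is None) and target is not None:
            placements = locate_occurrences(seq, target)
            if not placements:
                unmapped_rows.append(row)
                continue
            start, end = placements[0]
        if start is None or end is None:
            unmapped_rows.append(row)
            continue
        if target is not None and target[start - 1 : end] != seq:
            unmapped_rows.append(row)
            continue
        three = _termini_from_mod_text(row[cols["modifications"]]) if "modifications" in cols else "cyclic_phosphate"
        five = "OH" if start > 1 else "ppp"
        missed = max(0, sum(1 for i in range(start, end) if seq[i - start] in enzyme.cleaves_after))
        frag = TheoreticalFragment(
            start=start, end=end, sequence=seq, five_prime=five,
            three_prime=three, missed_cleavages=missed,
            neutral_mass=fragment_mass(seq, five, three),
        )
        conf = float(row[cols["confidence"]]) if "confidence" in cols and pd.notna(row[cols["confidence"]]) else 1.0
        if conf > 1.0:  # exported scores are often on a 0-100 scale
            conf /= 100.0
        rec = IdentificationRecord(
            fragment=frag,
            observed_mass=float(row[cols["observed_mass"]]) if "observed_mass" in cols and pd.notna(row[cols["observed_mass"]]) else frag.neutral_mass,
            delta_ppm=float(row[cols["delta_ppm"]]) if "delta_ppm" in cols and pd.notna(row[cols["delta_ppm"]]) else 0.0,
            confidence=conf,
            id_type=str(row[cols["id_type"]]) if "id_type" in cols and pd.notna(row[cols["id_type"]]) else "MS2",
            source_condition=str(row[cols["source_condition"]]) if "source_condition" in cols and pd.notna(row[cols["source_condition"]]) else source_condition,
            ms1_area=float(row[cols["ms1_area"]]) if "ms1_area" in cols and pd.notna(row[cols["ms1_area"]]) else 0.0,
        )
        if construct is not None:
            rec.uniqueness = classify_uniqueness(frag, construct, enzyme)
        records.append(rec)
    if unmapped_rows:
        logger.warning("%d row(s) could not be mapped to the construct",
                       len(unmapped_rows))
    return records, pd.DataFrame(unmapped_rows)


def export_id_table(records, path) -> None:
    """Write identification records as CSV (round-trips with import)."""
    records_to_frame(records).to_csv(path, index=False)
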