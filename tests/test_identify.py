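import numpy as np
import pandas as pd
import pytest

from conftest import make_fragment, make_record
from rnasemap.digest import enumerate_fragments
from rnasemap.identify import (
    FilterConfig,
    Spectrum,
    apply_filters,
    match_precursors,
    read_mgf,
    score_spectrum,
    write_mgf,
)
from rnasemap.masses import ms2_ions, mz


def peaks_frame(masses, intensity=100.0):
    return pd.DataFrame({"neutral_mass": masses,
                         "intensity": [intensity] * len(masses)})


def exact_spectrum(fragment, charges=(1, 2), spectrum_id="s1",
                   series=("c", "y", "w", "a-B")):
    ions = ms2_ions(fragment.sequence, fragment.five_prime,
                    fragment.three_prime, series=series, charges=charges)
    mzs = np.sort(np.array([i.mz for i in ions]))
    return Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=mz(fragment.neutral_mass, 1),
        precursor_charge=1,
        mz=mzs,
        intensity=np.ones(len(mzs)),
    )


class TestMatchPrecursors:
    def test_within_tolerance_single_match(self):
        cand = make_fragment("GGG")
        obs = cand.neutral_mass * (1 + 0.04e-6)
        recs = match_precursors(peaks_frame([obs]), [cand], tol_ppm=5.0)
        assert len(recs) == 1
        assert recs[0].delta_ppm == pytest.approx(0.04, abs=0.01)
        assert recs[0].ms1_area == 100.0

    def test_far_peak_does_not_match(self):
        cand = make_fragment("GGG")
        assert match_precursors(peaks_frame([2000.0]), [cand], tol_ppm=5.0) == []

    def test_ambiguity_preserved_between_isobaric_candidates(self):
        c1 = make_fragment("GGG")
        # second candidate shifted +10 ppm; peak equidistant between them
        c2 = make_fragment("GGG", start=10)
        object.__setattr__(c2, "neutral_mass", c1.neutral_mass * (1 + 10e-6))
        peak = c1.neutral_mass * (1 + 5e-6)
        recs = match_precursors(peaks_frame([peak]), [c1, c2], tol_ppm=20.0)
        assert len(recs) == 2

    def test_mz_with_charge_converted_to_neutral(self):
        cand = make_fragment("GGG")
        frame = pd.DataFrame(
            {"mz": [mz(cand.neutral_mass, 2)], "charge": [2], "intensity": [1.0]}
        )
        recs = match_precursors(frame, [cand], tol_ppm=5.0)
        assert len(recs) == 1
        assert recs[0].observed_mass == pytest.approx(cand.neutral_mass, abs=1e-6)

    def test_unusable_peak_skipped_with_warning(self, caplog):
        cand = make_fragment("GGG")
        frame = pd.DataFrame({"mz": [500.0], "charge": [np.nan], "intensity": [1.0]})
        with caplog.at_level("WARNING"):
            assert match_precursors(frame, [cand]) == []
        assert "skipping" in caplog.text

    def test_tolerance_nesting(self, rng):
        cands = [make_fragment(s) for s in ("GGG", "AUCG", "AAG", "CCG")]
        masses = [c.neutral_mass * (1 + rng.normal(0, 3e-6)) for c in cands]
        small = match_precursors(peaks_frame(masses), cands, tol_ppm=2.0)
        large = match_precursors(peaks_frame(masses), cands, tol_ppm=10.0)
        key = lambda r: (r.observed_mass, r.fragment.sequence)
        assert {key(r) for r in small} <= {key(r) for r in large}


class TestScoreSpectrum:
    def test_full_theoretical_set_scores_one(self):
        frag = make_fragment("AUCGAAG")
        assert score_spectrum(exact_spectrum(frag), frag) == pytest.approx(1.0)

    def test_disjoint_spectrum_scores_zero(self):
        frag = make_fragment("AUCGAAG")
        sp = Spectrum("s", mz(frag.neutral_mass, 1), 1,
                      mz=np.array([100.0, 120.0]), intensity=np.array([1.0, 1.0]))
        assert score_spectrum(sp, frag) == 0.0

    def test_half_ions_no_noise_scores_three_quarters(self):
        # restrict to c/y singly charged so every theoretical ion is distinct
        frag = make_fragment("AUCGAAG")
        full = exact_spectrum(frag, charges=(1,), series=("c", "y"))
        half = Spectrum("s", full.precursor_mz, 1,
                        mz=full.mz[::2], intensity=full.intensity[::2])
        got = score_spectrum(half, frag, series=("c", "y"), charges=(1,))
        assert got == pytest.approx(0.5 * (len(half.mz) / len(full.mz)) + 0.5,
                                    abs=1e-9)

    def test_single_residue_candidate_scores_zero(self):
        frag = make_fragment("G")
        sp = Spectrum("s", 100.0, 1, np.array([100.0]), np.array([1.0]))
        assert score_spectrum(sp, frag) == 0.0

    def test_true_candidates_separate_from_wrong_candidates(self, mrna_930):
        """Noiseless spectra score 1.0 on the generating fragment and low on
        sequence-scrambled alternatives."""
        frags = [f for f in enumerate_fragments(mrna_930, max_missed=2)
                 if 6 <= len(f.sequence) <= 20][:25]
        rng = np.random.default_rng(0)
        wrong_scores = []
        for f in frags:
            sp = exact_spectrum(f)
            assert score_spectrum(sp, f) == pytest.approx(1.0)
            scrambled = "".join(rng.permutation(list(f.sequence)))
            if scrambled == f.sequence:
                continue
            wrong = make_fragment(scrambled, three_prime=f.three_prime)
            wrong_scores.append(score_spectrum(sp, wrong))
        assert np.median(wrong_scores) < 0.2


class TestApplyFilters:
    def test_ppm_window(self):
        rec = make_record("AUCG", delta_ppm=25.0)
        kept, report = apply_filters([rec], FilterConfig())
        assert kept == [] and report["ppm_window"] == 1

    def test_nonunique_removed(self):
        rec = make_record("AAG", uniqueness="nonunique", occurrences=2)
        kept, report = apply_filters([rec], FilterConfig())
        assert kept == [] and report["nonunique"] == 1

    def test_ms1_only_removed_when_ms2_required(self):
        rec = make_record("AUCG", id_type="MS1-only", confidence=1.0)
        kept, report = apply_filters([rec], FilterConfig())
        assert kept == [] and report["require_ms2"] == 1
        kept2, _ = apply_filters([rec], FilterConfig(require_ms2=False))
        assert kept2 == [rec]

    def test_low_confidence_removed(self):
        rec = make_record("AUCG", confidence=0.5)
        kept, report = apply_filters([rec])
        assert kept == [] and report["confidence"] == 1

    def test_nonspecific_removed(self):
        rec = make_record("AUCG", uniqueness="nonspecific", occurrences=0)
        kept, report = apply_filters([rec])
        assert kept == [] and report["nonspecific"] == 1

    def test_passing_record_kept_in_order(self):
        recs = [make_record("AUCG"), make_record("AAG", start=5)]
        kept, report = apply_filters(recs)
        assert kept == recs
        assert all(v == 0 for v in report.values())

    def test_idempotent(self):
        recs = [make_record("AUCG"), make_record("AAG", confidence=0.2),
                make_record("CCG", delta_ppm=30.0)]
        once, _ = apply_filters(recs)
        twice, _ = apply_filters(once)
        assert once == twice

    def test_monotone_in_criteria(self):
        recs = [
            make_record("AUCG"),
            make_record("AAG", id_type="MS1-only"),
            make_record("CCG", uniqueness="nonunique", occurrences=3),
            make_record("UUG", confidence=0.3),
        ]
        lax = FilterConfig(require_specific=False, max_nonunique_placements=99,
                           ppm_window=100, min_confidence=0.0,
                           require_ms2=False, require_observed_mass=False)
        strict = FilterConfig()
        kept_lax, _ = apply_filters(recs, lax)
        kept_strict, _ = apply_filters(recs, strict)
        assert set(map(id, kept_strict)) <= set(map(id, kept_lax))


class TestMgfRoundTrip:
    def test_write_then_read_preserves_spectra(self, tmp_path):
        frag = make_fragment("AUCGAAG")
        sp = exact_spectrum(frag, spectrum_id="roundtrip-1")
        path = tmp_path / "test.mgf"
        write_mgf([sp], path)
        back = read_mgf(path)
        assert len(back) == 1
        got = back[0]
        assert got.spectrum_id == "roundtrip-1"
        assert got.precursor_charge == 1
        assert got.precursor_mz == pytest.approx(sp.precursor_mz, abs=1e-5)
        np.testing.assert_allclose(got.mz, sp.mz, atol=1e-5)
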