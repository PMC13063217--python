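import pytest
from hypothesis import given
from hypothesis import strategies as st
from pyteomics import mass as pt_mass

from rnasemap.construct import CAP1_AG
from rnasemap.masses import (
    ElementalComposition,
    H2O,
    HPO3,
    MONOISOTOPIC_ELEMENT_MASSES,
    NUCLEOBASE_COMPOSITIONS,
    PROTON_MASS,
    RESIDUE_COMPOSITIONS,
    fragment_composition,
    fragment_mass,
    monoisotopic_mass,
    ms2_ions,
    mz,
    neutral_mass_from_mz,
    ppm_error,
)

H2O_MASS = 18.0105646863
HPO3_MASS = 79.9663305

rna = st.text(alphabet="ACGUY", min_size=2, max_size=40)
termini3 = st.sampled_from(["OH", "cyclic_phosphate", "linear_phosphate"])
termini5 = st.sampled_from(["OH", "p", "pp", "ppp"])


def oracle_mass(formula: str) -> float:
    """Independent atomic-mass-sum oracle (pyteomics NIST table)."""
    return pt_mass.calculate_mass(formula=formula)


class TestElementalComposition:
    def test_formula_parse_and_hill_order(self):
        c = ElementalComposition("C10H12N5O6P")
        assert c == {"C": 10, "H": 12, "N": 5, "O": 6, "P": 1}
        assert c.formula() == "C10H12N5O6P"

    def test_arithmetic(self):
        a = ElementalComposition("H2O") + ElementalComposition("HPO3")
        assert a == {"H": 3, "O": 4, "P": 1}
        assert 2 * HPO3 == {"H": 2, "P": 2, "O": 6}
        assert (a - H2O) == HPO3

    def test_subtraction_never_goes_negative(self):
        with pytest.raises(ValueError, match="negative"):
            H2O - HPO3

    def test_bad_formula_rejected(self):
        with pytest.raises(ValueError):
            ElementalComposition("C10x")


class TestAtomicMassTable:
    def test_elements_agree_with_independent_table(self):
        for el, m in MONOISOTOPIC_ELEMENT_MASSES.items():
            assert abs(m - pt_mass.nist_mass[el][0][0]) < 1e-6

    @pytest.mark.parametrize("formula,expected", [("H2O", 18.010565), ("HPO3", 79.96633)])
    def test_small_molecules(self, formula, expected):
        assert monoisotopic_mass(ElementalComposition(formula)) == pytest.approx(
            expected, abs=1e-5
        )

    def test_empty_composition_is_massless(self):
        assert monoisotopic_mass(ElementalComposition()) == 0.0

    def test_average_mass_exceeds_monoisotopic_for_polyatomics(self):
        comp = RESIDUE_COMPOSITIONS["G"]
        assert comp.average > comp.monoisotopic


class TestResidueTable:
    # Internal-residue monoisotopic masses, frozen against the atomic-mass
    # oracle (nucleoside monophosphate minus water).
    @pytest.mark.parametrize(
        "symbol,expected",
        [("A", 329.05252), ("C", 305.04129), ("G", 345.04744),
         ("U", 306.02530), ("Y", 320.04095)],
    )
    def test_internal_residue_masses(self, symbol, expected):
        comp = RESIDUE_COMPOSITIONS[symbol]
        assert comp.monoisotopic == pytest.approx(expected, abs=1e-4)
        assert comp.monoisotopic == pytest.approx(
            oracle_mass(comp.formula()), abs=1e-6
        )

    def test_m1psi_is_uridine_plus_methylene(self):
        assert RESIDUE_COMPOSITIONS["Y"] == RESIDUE_COMPOSITIONS["U"] + ElementalComposition("CH2")

    def test_2prime_methyl_adds_methylene(self):
        for b in "ACGUY":
            assert (RESIDUE_COMPOSITIONS[b.lower()]
                    == RESIDUE_COMPOSITIONS[b] + ElementalComposition("CH2"))

    def test_nucleobases_agree_with_oracle(self):
        for comp in NUCLEOBASE_COMPOSITIONS.values():
            assert comp.monoisotopic == pytest.approx(
                oracle_mass(comp.formula()), abs=1e-6
            )


class TestFragmentMass:
    def test_triguanylate_baseline(self):
        assert fragment_mass("GGG", "OH", "OH") == pytest.approx(1053.15288, abs=1e-4)

    def test_cyclic_phosphate_delta(self):
        base = fragment_mass("GGG", "OH", "OH")
        cyc = fragment_mass("GGG", "OH", "cyclic_phosphate")
        assert cyc - base == pytest.approx(61.95577, abs=1e-4)

    def test_linear_minus_cyclic_is_one_water(self):
        lin = fragment_mass("AUCG", "OH", "linear_phosphate")
        cyc = fragment_mass("AUCG", "OH", "cyclic_phosphate")
        assert lin - cyc == pytest.approx(H2O_MASS, abs=1e-6)

    @given(rna, termini5, termini3)
    def test_composition_and_float_paths_agree(self, seq, t5, t3):
        comp = fragment_composition(seq, t5, t3)
        assert fragment_mass(seq, t5, t3) == pytest.approx(
            comp.monoisotopic, abs=1e-9
        )
        assert comp.monoisotopic == pytest.approx(
            oracle_mass(comp.formula()), abs=1e-5
        )

    @given(rna, rna, termini5, termini3)
    def test_phosphodiester_condensation_additivity(self, s1, s2, t5, t3):
        # joining two pieces through the backbone releases one water
        joined = fragment_mass(s1 + s2, t5, t3)
        assert joined == pytest.approx(
            fragment_mass(s1, t5, "OH") + fragment_mass(s2, "OH", t3) - H2O_MASS,
            abs=1e-6,
        )

    def test_cap1_delta_matches_oracle(self):
        capped = fragment_composition("AG", CAP1_AG, "cyclic_phosphate")
        assert capped.monoisotopic == pytest.approx(
            oracle_mass(capped.formula()), abs=1e-5
        )
        plain = fragment_composition("AG", "OH", "cyclic_phosphate")
        delta = capped.monoisotopic - plain.monoisotopic
        # m7G + triphosphate bridge + one 2'-O-methyl
        expected = (CAP1_AG.formula_delta.monoisotopic
                    + ElementalComposition("CH2").monoisotopic)
        assert delta == pytest.approx(expected, abs=1e-6)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="unknown residue"):
            fragment_mass("AXG")


class TestMz:
    def test_doubly_charged_triguanylate(self):
        m = fragment_mass("GGG", "OH", "cyclic_phosphate")
        assert mz(m, 2) == pytest.approx((m - 2 * PROTON_MASS) / 2, abs=1e-9)
        assert mz(m, 2) == pytest.approx(556.54704, abs=1e-4)

    def test_water_singly_charged(self):
        assert mz(H2O_MASS, 1) == pytest.approx(17.003288, abs=1e-5)

    def test_charge_identity(self):
        m = 2500.0
        assert mz(m, 1) - 2 * mz(m, 2) == pytest.approx(PROTON_MASS, abs=1e-9)

    def test_zero_charge_rejected(self):
        with pytest.raises(ValueError):
            mz(100.0, 0)

    @given(st.floats(500, 30000), st.integers(1, 20))
    def test_mz_roundtrip(self, m, z):
        assert neutral_mass_from_mz(mz(m, z), z) == pytest.approx(m, rel=1e-12)


class TestPpmError:
    def test_five_ppm(self):
        theo = 1115.10865
        obs = theo * (1 + 5e-6)
        assert ppm_error(obs, theo) == pytest.approx(5.0, abs=1e-6)

    def test_equal_masses(self):
        assert ppm_error(100.0, 100.0) == 0.0

    def test_swap_antisymmetry_is_approximate(self):
        a, b = 1000.0, 1000.01
        assert ppm_error(a, b) != -ppm_error(b, a)
        assert ppm_error(a, b) == pytest.approx(-ppm_error(b, a), rel=1e-4)


class TestMs2Ions:
    def test_series_and_count_for_tetramer(self):
        ions = ms2_ions("AUCG", "OH", "cyclic_phosphate",
                        series=("c", "y"), charges=(1,))
        assert len(ions) == 6  # 3 cleavage ordinals x 2 series
        assert all(ion.mz > 0 for ion in ions)
        assert {ion.series for ion in ions} == {"c", "y"}

    def test_short_fragments_yield_no_ions(self):
        assert ms2_ions("A") == []

    @given(rna, termini5, termini3)
    def test_cy_complementarity(self, seq, t5, t3):
        n = len(seq)
        M = fragment_mass(seq, t5, t3)
        ions = ms2_ions(seq, t5, t3, series=("c", "y"), charges=(1,))
        c = {i.index: i.neutral_mass for i in ions if i.series == "c"}
        y = {i.index: i.neutral_mass for i in ions if i.series == "y"}
        for i in range(1, n):
            assert c[i] + y[n - i] == pytest.approx(M + H2O_MASS, abs=1e-6)

    @given(rna)
    def test_w_is_y_plus_phosphate(self, seq):
        ions = ms2_ions(seq, "OH", "cyclic_phosphate",
                        series=("y", "w"), charges=(1,))
        y = {i.index: i.neutral_mass for i in ions if i.series == "y"}
        w = {i.index: i.neutral_mass for i in ions if i.series == "w"}
        for j in y:
            assert w[j] - y[j] == pytest.approx(HPO3_MASS, abs=1e-6)

    @given(rna)
    def test_aB_loses_base_from_a(self, seq):
        ions = ms2_ions(seq, "OH", "cyclic_phosphate",
                        series=("c", "a-B"), charges=(1,))
        c = {i.index: i.neutral_mass for i in ions if i.series == "c"}
        ab = {i.index: i.neutral_mass for i in ions if i.series == "a-B"}
        for i in ab:
            base = NUCLEOBASE_COMPOSITIONS[seq[i - 1]].monoisotopic
            assert ab[i] == pytest.approx(c[i] - HPO3_MASS - base, abs=1e-6)

    @given(rna, st.integers(1, 4))
    def test_mz_consistent_with_charging(self, seq, z):
        for ion in ms2_ions(seq, charges=(z,)):
            assert ion.mz == pytest.approx(mz(ion.neutral_mass, z), abs=1e-9)
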