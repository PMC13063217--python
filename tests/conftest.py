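import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rnasemap.construct import MrnaConstruct
from rnasemap.digest import TheoreticalFragment, UniquenessClass
from rnasemap.identify import IdentificationRecord
from rnasemap.masses import fragment_mass

settings.register_profile(
    "package",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture
def small_construct():
    """8-mer with two internal T1 sites (after positions 4 and 7)."""
    return MrnaConstruct(name="small", sequence="AUCGAAGU")


@pytest.fixture(scope="session")
def mrna_930():
    """Reporter-sized random fixture: 860 nt body + 70 nt poly(A) tail."""
    from rnasemap.simulate import random_construct

    return random_construct(length=930, seed=11, polyA_length=70)


def make_fragment(
    sequence: str,
    start: int = 1,
    five_prime: str = "OH",
    three_prime: str = "cyclic_phosphate",
    missed: int = 0,
) -> TheoreticalFragment:
    return TheoreticalFragment(
        start=start,
        end=start + len(sequence) - 1,
        sequence=sequence,
        five_prime=five_prime,
        three_prime=three_prime,
        missed_cleavages=missed,
        neutral_mass=fragment_mass(sequence, five_prime, three_prime),
    )


def make_record(
    sequence: str,
    start: int = 1,
    uniqueness: str = "unique",
    occurrences: int = 1,
    confidence: float = 1.0,
    id_type: str = "MS2",
    delta_ppm: float = 0.0,
    source: str = "",
    three_prime: str = "cyclic_phosphate",
) -> IdentificationRecord:
    frag = make_fragment(sequence, start, three_prime=three_prime)
    return IdentificationRecord(
        fragment=frag,
        observed_mass=frag.neutral_mass,
        delta_ppm=delta_ppm,
        confidence=confidence,
        id_type=id_type,
        uniqueness=UniquenessClass(uniqueness, occurrences),
        source_condition=source,
        ms1_area=1.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
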