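import numpy as np
import pytest

from unidem import synthetic_data
from unidem.haplotype_io import HaplotypeMatrix, Site


def make_matrix(rows, label="synthetic", sample_ids=None):
    """Build a HaplotypeMatrix from strings of 0/1/N."""
    geno = np.array(
        [[-1 if ch == "N" else int(ch) for ch in row] for row in rows],
        dtype=np.int8,
    )
    return HaplotypeMatrix(
        sample_ids=sample_ids or [f"h{i + 1}" for i in range(len(rows))],
        sites=[Site(j + 1, "A", "G") for j in range(geno.shape[1])],
        genotypes=geno,
        locus_label=label,
    )


@pytest.fixture(scope="session")
def fixtures():
    return synthetic_data.worked_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_study_populations():
    """A small HGDP-shaped panel for pipeline tests (68 samples, 15 pops)."""
    return [
        ("PopAf1", "Africa", 6, 0.0, 20.0, False),
        ("PopAf2", "Africa", 6, -10.0, 25.0, False),
        ("PopOc1", "Oceania", 3, -6.0, 155.0, False),
        ("PopOc2", "Oceania", 3, -4.0, 143.0, False),
        ("PopEu1", "Europe", 5, 46.0, 2.0, False),
        ("PopEu2", "Europe", 5, 40.0, 9.0, False),
        ("Adygei", "Europe", 4, 44.0, 39.0, True),
        ("PopCa1", "Central Asia", 5, 30.0, 66.0, False),
        ("PopCa2", "Central Asia", 5, 36.0, 74.0, False),
        ("PopEa1", "East Asia", 6, 32.0, 114.0, False),
        ("PopEa2", "East Asia", 6, 38.0, 138.0, False),
        ("PopAm1", "America", 3, -10.0, -63.0, False),
        ("PopAm2", "America", 3, 19.0, -91.0, False),
        ("PopMe1", "ME/NA", 4, 31.0, 35.0, False),
        ("PopMe2", "ME/NA", 4, 32.0, 3.0, False),
    ]
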