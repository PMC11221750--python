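import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import admixqc as aq
from admixqc.containers import make_markers

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

CHROM_LENGTHS = {f"chr{i}": 50_000_000 for i in range(1, 5)}


@pytest.fixture(scope="session")
def gmap():
    return aq.uniform_map(CHROM_LENGTHS, rate=1e-8)


@pytest.fixture(scope="session")
def freqs():
    """Default synthetic founder frequencies: F_ST 0.4, 0.5% fixed."""
    return aq.simulate_founder_frequencies(
        4000, fst_target=0.4, fixed_fraction=0.005, chrom_lengths=CHROM_LENGTHS, seed=101
    )


@pytest.fixture(scope="session")
def founder_sim(freqs):
    return aq.simulate_founders(freqs, (9, 9), seed=102)


@pytest.fixture(scope="session")
def pedigree_sim(freqs, gmap):
    design = {
        "founders": {"olive": 9, "yellow": 9},
        "crosses": [
            ("F1_001", "OLV001", "YEL001"),
            ("F1_002", "OLV002", "YEL002"),
            ("BC_001", "F1_001", "OLV003"),
            ("F2_001", "F1_001", "F1_002"),
        ],
    }
    return aq.simulate_pedigree(design, freqs, gmap, seed=103)


def informative_freqs(n_markers=200, chrom_lengths=None, spacing=100_000):
    """Fully informative frequencies: olive fixed alt, yellow fixed ref."""
    chrom_lengths = chrom_lengths or {"chr1": (n_markers + 1) * spacing}
    per = n_markers // len(chrom_lengths)
    chroms, pos = [], []
    for c in chrom_lengths:
        chroms += [c] * per
        pos += [(k + 1) * spacing for k in range(per)]
    mk = make_markers(chroms, pos)
    freq = np.column_stack([np.ones(len(mk)), np.zeros(len(mk))])
    return aq.PopulationFrequencies(mk, freq, np.full(len(mk), 0.5))
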