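import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from poolscreen import GuideLibrary, SimConfig, simulate_screen

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def toy_library() -> GuideLibrary:
    """Two genes, 2 + 1 guides, distinct 20-nt spacers."""
    return GuideLibrary(
        pd.DataFrame(
            {
                "guide_id": ["gA1", "gA2", "gB1"],
                "gene": ["GENEA", "GENEA", "GENEB"],
                "spacer": [
                    "AACCGGTTAACCGGTTAACC",
                    "TTTTCCCCAAAAGGGGTTTT",
                    "GATTACAGATTACAGATTAC",
                ],
            }
        )
    )


@pytest.fixture
def toy_counts(toy_library) -> pd.DataFrame:
    counts = pd.DataFrame(
        {"dmso": [100, 80, 120], "drug": [50, 30, 240]},
        index=toy_library.guide_ids,
        dtype=np.int64,
    )
    counts.index.name = "guide_id"
    return counts


@pytest.fixture(scope="session")
def small_sim():
    """One seeded small screen shared by read-only tests."""
    return simulate_screen(SimConfig(n_genes=200, n_sensitizers=8, n_resistance=8, seed=7))


def make_fastq(path, sequences, quality_char="I"):
    """Write a minimal plain-text FASTQ from raw sequences."""
    with open(path, "w") as handle:
        for i, seq in enumerate(sequences):
            handle.write(f"@read{i}\n{seq}\n+\n{quality_char * len(seq)}\n")
    return path
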