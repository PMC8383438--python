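import numpy as np
import pandas as pd
import pytest

from atacdiff.simulate import SampleSpec, SimulationConfig, simulate_dataset


def two_group_design(n_per_group: int, cell_fraction: str = "non_neuronal",
                     sex: str = "F") -> list[SampleSpec]:
    """Unpaired single-fraction case/control design for calibration studies."""
    specs = []
    for i in range(n_per_group):
        specs.append(SampleSpec(f"C{i:03d}_S", f"C{i:03d}", cell_fraction, "control", sex))
    for i in range(n_per_group):
        specs.append(SampleSpec(f"L{i:03d}_S", f"L{i:03d}", cell_fraction, "mild_LOAD", sex))
    return specs


@pytest.fixture(scope="session")
def small_dataset():
    """One deterministic full synthetic dataset shared across tests."""
    cfg = SimulationConfig(n_peaks=800, seed=11)
    peaks, metadata, counts, regions, truth = simulate_dataset(cfg)
    return {
        "cfg": cfg,
        "peaks": peaks,
        "metadata": metadata,
        "counts": counts,
        "regions": regions,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=5000, max_len=120) -> pd.DataFrame:
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return pd.DataFrame(
        {
            "chrom": rng.choice(chroms, size=n),
            "start": starts,
            "end": starts + lengths,
        }
    )
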