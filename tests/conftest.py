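import numpy as np
import pytest

from mirnapipe import synthetic_data as sd
from mirnapipe.smallrna_quant import MiRNACountMatrix


@pytest.fixture(scope="session")
def reference():
    """Small substring-free reference with all five contaminant classes."""
    return sd.make_reference(20, 5, seed=11)


@pytest.fixture
def two_group_design():
    return sd.make_design({"A": 3, "B": 3})


@pytest.fixture
def small_counts(reference, two_group_design):
    """Deterministic Poisson counts with one 8-fold spike in group A."""
    truth = sd.SimulationTruth(
        spiked={"syn-miR-001": sd.Spike(group="A", fold=8.0)},
        library_sizes={s: 50_000 for s in two_group_design},
        seed=5,
    )
    counts, _ = sd.simulate_counts(
        reference, two_group_design, truth, baseline_mean=200.0, dispersion=0.0
    )
    return counts


@pytest.fixture
def tiny_matrix():
    rng = np.random.default_rng(3)
    counts = rng.integers(0, 50, size=(20, 6))
    samples = [f"s{j}" for j in range(6)]
    return MiRNACountMatrix(
        mirna_ids=[f"m{i}" for i in range(20)],
        sample_ids=samples,
        counts=counts,
        clean_totals={s: 10_000 for s in samples},
    )
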