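import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from masqc import (
    ModificationCall,
    Peak,
    SimulationConfig,
    generate_genome,
    plant_motifs_and_calls,
    simulate_peaks,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


def make_call(
    chrom="chr1",
    position=101,
    strand="+",
    ipd_ratio=4.8,
    coverage=60,
    score=35.0,
    fraction=0.9,
    **kwargs,
):
    return ModificationCall(
        chrom=chrom,
        position=position,
        strand=strand,
        ipd_ratio=ipd_ratio,
        coverage=coverage,
        score=score,
        fraction=fraction,
        **kwargs,
    )


def make_peak(chrom="chr1", start=100, end=150, enrichment=5.2, neg_log10_q=13.0,
              **kwargs):
    return Peak(chrom=chrom, start=start, end=end, enrichment=enrichment,
                neg_log10_q=neg_log10_q, **kwargs)


@pytest.fixture(scope="session")
def prokaryote_dataset():
    """One prokaryote-like synthetic dataset shared across tests."""
    config = SimulationConfig.prokaryote_like(seed=11)
    genome, calls, truth = plant_motifs_and_calls(generate_genome(config), config)
    peaks = simulate_peaks(truth, genome, config)
    return config, genome, calls, truth, peaks


@pytest.fixture(scope="session")
def eukaryote_dataset():
    config = SimulationConfig.eukaryote_like(seed=11)
    genome, calls, truth = plant_motifs_and_calls(generate_genome(config), config)
    peaks = simulate_peaks(truth, genome, config)
    return config, genome, calls, truth, peaks


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
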