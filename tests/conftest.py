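import pytest

from trarep import (
    SimulationConfig,
    annotate_reads,
    build_clonotypes,
    build_mock_reference,
    simulate_sample,
)


@pytest.fixture(scope="session")
def mock_ref():
    """Standard 12V x 8J mock reference used across the suite."""
    return build_mock_reference(12, 8, seed=7)


@pytest.fixture(scope="session")
def tiny_ref():
    return build_mock_reference(5, 5, seed=3)


@pytest.fixture(scope="session")
def clean_sample(mock_ref):
    """A small error-free sample with its truth and annotations."""
    config = SimulationConfig(n_clones=40, n_reads=2000, error_rate=0.0, seed=11)
    reads, truth = simulate_sample(config, mock_ref, "clean")
    annotations = annotate_reads(reads, mock_ref)
    return config, reads, truth, annotations


@pytest.fixture(scope="session")
def clean_profile(clean_sample):
    _, _, _, annotations = clean_sample
    return build_clonotypes(annotations, "clean")
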