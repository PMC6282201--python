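import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

from twinmag.synthetic_data import (
    GenomeSpec,
    TwinDesign,
    fragment_genomes,
    generate_genomes,
    simulate_coverage,
)


@pytest.fixture(scope="session")
def small_mixture():
    """Three compositionally distinct 120-kb genomes, fragmented and covered
    across 20 subjects; enough for seed binning and abundance tests."""
    specs = [
        GenomeSpec(f"g{i}", length=120_000, gc_target=gc)
        for i, gc in enumerate([0.30, 0.50, 0.70])
    ]
    genomes = generate_genomes(specs, seed=42)
    contigs = fragment_genomes(genomes, seed=42)
    design = TwinDesign(n_mz_pairs=5, n_dz_pairs=5, ace=(0.5, 0.2, 0.3), seed=42)
    coverage, metadata, latent = simulate_coverage(contigs, design, depth=50.0)
    return {
        "specs": specs,
        "genomes": genomes,
        "contigs": contigs,
        "coverage": coverage,
        "metadata": metadata,
        "latent": latent,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
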