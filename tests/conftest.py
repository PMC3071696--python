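import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from hoxchip.synthetic import (ArrayConfig, GenomeSpec, PlantConfig,
                               generate_accessibility, generate_genome,
                               plant_bound_regions,
                               simulate_probe_intensities)


@pytest.fixture(scope="session")
def small_genome():
    """200 kb single-chromosome genome with genes, shared across tests."""
    spec = GenomeSpec(chromosomes=[("chr1", 200_000)], seed=7)
    sequences, genes = generate_genome(spec)
    return spec, sequences, genes


@pytest.fixture(scope="session")
def planted_study():
    """A small constrained study: genome, domains, regions, probe panels."""
    spec = GenomeSpec(chromosomes=[("chr1", 400_000), ("chr2", 200_000)], seed=11)
    sequences, genes = generate_genome(spec)
    lengths = dict(spec.chromosomes)
    domains = generate_accessibility(lengths, 8, 0.3, seed=11)
    cfg = PlantConfig(n_single=15, n_clusters=2, half_width_bp=500,
                      fold_min=8.0, fold_max=8.0, constrained=True)
    regions = plant_bound_regions(genes, domains, cfg, seed=11)
    specific, control = simulate_probe_intensities(lengths, regions,
                                                   ArrayConfig(), seed=11)
    return {
        "spec": spec, "sequences": sequences, "genes": genes,
        "lengths": lengths, "domains": domains, "regions": regions,
        "specific": specific, "control": control,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(42)
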