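import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from readpref.context import ContextConfig
from readpref.countdata import GeneCounts
from readpref.simulate import LinearPreference, SimConfig, simulate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def planted_linear() -> LinearPreference:
    """A moderately strong planted log-linear preference over a (3,3) window."""
    cfg = ContextConfig(3, 3)
    rng = np.random.default_rng(42)
    beta = rng.normal(0.0, 0.3, 3 * cfg.K)
    return LinearPreference(0.0, beta, cfg)


@pytest.fixture(scope="session")
def small_dataset(planted_linear):
    """10 genes with planted linear preferences: (genes, truth)."""
    sim = SimConfig(
        n_genes=10,
        region_length_range=(150, 250),
        flank_length=10,
        preference_spec=planted_linear,
        seed=5,
    )
    return simulate_dataset(sim)


def make_gene(gene_id: str, sequence: str, counts, flank: int = 0) -> GeneCounts:
    """GeneCounts whose region is the whole sequence minus symmetric flanks."""
    return GeneCounts(
        gene_id, sequence, flank, len(sequence) - flank, np.asarray(counts)
    )
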