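import numpy as np
import pytest

from embryomark.simulate import PlantedPattern, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_config():
    """Seconds-scale dataset: 2 x 1 Mb, 4 tissues x 2 reps, 300 genes."""
    tissues = ("heart", "brain", "liver", "kidney")
    pats = tuple(PlantedPattern("H3K27ac", (t,), 60) for t in tissues) + (
        PlantedPattern("H3K27ac", tissues, 40),)
    return SimConfig(
        n_chroms=2, chrom_length=1_000_000,
        tissues=tissues, planted_patterns=pats,
        n_genes=300, enhancer_target_pairs=10,
        n_dnm_regions=400, seed=7,
    )
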