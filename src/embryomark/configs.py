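"""Named study-condition configurations for the individual analyses.

The default :class:`~embryomark.simulate.SimConfig` carries the scaled-down
promoter-state dataset (5,000 genes, 6 tissues x 2 replicates on a 2 x 5 Mb
toy genome).  The correlation and DNM analyses have their own stated
conditions - window gene density, tissue count, mutation counts - which
these constructors pin down in one place so the analysis drivers, the tests
and the acceptance script all run the same experiment.
"""

from __future__ import annotations

from .simulate import DEFAULT_TISSUES, PlantedPattern, SimConfig

__all__ = ["default_config", "correlation_study_config", "dnm_study_config",
           "dnm_null_config"]


def default_config(seed=0, **overrides):
    """Scaled promoter-state / pattern dataset: 5,000 genes, 6 tissues x 2."""
    return SimConfig(seed=seed, **overrides)


def correlation_study_config(seed=0):
    """Enhancer-target correlation conditions: 12 tissues, ~44 genes per
    2 Mb window, 40 planted pairs at coupling 0.9."""
    tissues = tuple(f"t{i:02d}" for i in range(12))
    return SimConfig(
        tissues=tissues,
        n_genes=220,
        enhancer_target_pairs=40,
        coupling_r=0.9,
        planted_patterns=tuple(
            PlantedPattern("H3K27ac", (t,), 200) for t in tissues),
        seed=seed,
    )


def dnm_study_config(seed=0):
    """DNM enrichment conditions: sparse marked elements (~10% of surveyed
    bases after +/- 1 kb expansion) and per-base rates in the 1.45 ratio,
    scaled so the surveyed territory yields several hundred mutations."""
    pats = [PlantedPattern("H3K27ac", (t,), 50) for t in DEFAULT_TISSUES]
    pats.append(PlantedPattern("H3K27ac", DEFAULT_TISSUES, 30))
    return SimConfig(
        planted_patterns=tuple(pats),
        enhancer_target_pairs=0,
        n_genes=200,
        dnm_rate_marked=8.7e-4,
        dnm_rate_unmarked=6.0e-4,
        seed=seed,
    )


def dnm_null_config(seed=0):
    """As :func:`dnm_study_config` but with equal rates (no enrichment)."""
    cfg = dnm_study_config(seed)
    return SimConfig(**{**cfg.__dict__,
                        "dnm_rate_marked": 6.0e-4,
                        "dnm_rate_unmarked": 6.0e-4})
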