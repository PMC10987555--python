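import numpy as np
import pandas as pd
import pytest

from eduseq import (
    BinnedGenome,
    BinnedTrack,
    SimulationConfig,
    simulate_control,
    simulate_edu_hu,
    sigma_from_tracks,
)


@pytest.fixture(scope="session")
def toy_genome() -> BinnedGenome:
    """Two short chromosomes with a truncated final bin on chr2."""
    return BinnedGenome(("chr1", "chr2"), (100_000, 55_000), bin_size=10_000)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def hu_experiment(default_config):
    """Control + NE/OE HU-arrest sigma tracks with planted truth (seed 1)."""
    cfg = default_config
    control = simulate_control(cfg)
    edu_ne, truth = simulate_edu_hu(cfg, "NE", genotype="WT")
    edu_oe, _ = simulate_edu_hu(cfg, "OE", genotype="WT", truth=truth)
    return {
        "config": cfg,
        "control": control,
        "truth": truth,
        "sigma_NE": sigma_from_tracks(edu_ne, control),
        "sigma_OE": sigma_from_tracks(edu_oe, control),
    }


def uniform_track(genome: BinnedGenome, value: int, **kwargs) -> BinnedTrack:
    return BinnedTrack(genome, np.full(genome.n_bins, value, dtype=np.int64), **kwargs)


def loci_frame(*entries) -> pd.DataFrame:
    """(chrom, bin, summit_bp) tuples -> locus DataFrame."""
    return pd.DataFrame(entries, columns=["chrom", "bin", "summit_bp"])
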