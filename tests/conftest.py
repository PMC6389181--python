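import numpy as np
import pytest

from cisnat.simulate import SimulationConfig, make_annotation, simulate_counts, write_experiment


@pytest.fixture(scope="session")
def small_config():
    """A small mixed experiment: isolated loci plus planted overlapping pairs."""
    return SimulationConfig(
        n_single_loci=10,
        n_opposite_overlap_pairs=2,
        n_same_strand_overlap_pairs=1,
        conditions=("Cd_50uM",),
        timepoints=(0, 24),
        replicates_per_sample=2,
        baseline_sense_mean=80.0,
        baseline_antisense_mean=15.0,
        dispersion=0.05,
        seed=11,
        effect_table={
            ("SYNG00001-01", "antisense", "Cd_50uM", 24): 10.0,
            ("SYNG00001-01", "sense", "Cd_50uM", 24): 10.0,
            ("SYNG00002-01", "antisense", "Cd_50uM", 24): 10.0,
        },
    )


@pytest.fixture(scope="session")
def small_experiment(small_config, tmp_path_factory):
    """The small experiment materialised on disk (GFF3, SAMs, design, truth)."""
    out = tmp_path_factory.mktemp("experiment")
    result = write_experiment(small_config, out)
    result["out_dir"] = out
    result["config"] = small_config
    return result


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
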