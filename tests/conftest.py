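import numpy as np
import pandas as pd
import pytest

from sweepscan.io import GenotypeDataset


def make_dataset(genotypes, groups, positions=None, contig="chr1", contig_length=None):
    """Build a GenotypeDataset from a (n_samples, n_variants, 2) array.

    ``groups``: list of group labels, one per sample.
    """
    g = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_variants, _ = g.shape
    if positions is None:
        positions = np.arange(1, n_variants + 1) * 100
    samples = [f"{grp}_{i}" for i, grp in enumerate(groups)]
    variants = pd.DataFrame(
        {
            "contig": [contig] * n_variants,
            "pos": positions,
            "ref": ["A"] * n_variants,
            "alt": ["G"] * n_variants,
        }
    )
    return GenotypeDataset(
        variants=variants,
        genotypes=g,
        samples=samples,
        group_of=dict(zip(samples, groups)),
        contig_lengths={contig: contig_length or int(positions[-1]) + 100},
        phased=True,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_cohort():
    """A tiny simulated cohort used by several integration tests."""
    from sweepscan.simulate import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        n_contigs=1,
        contig_length=400_000,
        n_regions_per_scenario={"uni_introgression": 2, "bidirectional": 2, "neutral": 4},
        samples_per_group={"CHW": 12, "CHD": 12, "EUW": 12, "EUD": 12, "AP": 1},
        seed=7,
    )
    return simulate_cohort(cfg)
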