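import numpy as np
import pytest

import phaseblocks as pb
from phaseblocks.datasets import toy_switch_example


@pytest.fixture(scope="session")
def toy():
    """The 10-het-SNP worked example: (truths dict, estimate panel)."""
    return toy_switch_example()


@pytest.fixture(scope="session")
def toy_profiles(toy):
    truths, est = toy
    return pb.panel_profiles(truths, est)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def all_het_truth_panel(n_individuals: int, n_sites: int, seed: int) -> pb.HaplotypePanel:
    """A phased panel in which every individual is heterozygous everywhere
    (copy 2 is the complement of a random copy 1)."""
    r = np.random.default_rng(seed)
    c1 = r.integers(0, 2, size=(n_individuals, n_sites), dtype=np.int8)
    alleles = np.stack([c1, 1 - c1], axis=2)
    samples = [f"i{k}" for k in range(n_individuals)]
    return pb.HaplotypePanel(samples, pb.VariantMap.default(n_sites), alleles)
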