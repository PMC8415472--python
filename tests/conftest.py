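import numpy as np
import pytest

from quantphylo.properties import GappedSequence, encode_alignment
from quantphylo.simulate import FamilyConfig, evolve_family


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def toy_alignment():
    """Three aligned 12-residue sequences with one gap column."""
    return [
        GappedSequence("alpha", "MKT-AYIAKQRG"),
        GappedSequence("beta", "MKT-AYIAKQRA"),
        GappedSequence("gamma", "MRT-AYVAKQRG"),
    ]


@pytest.fixture
def paired_family():
    """A synthetic ((A,B),(C,D)) family: tight pairs, wide cross-pair split."""
    config = FamilyConfig(
        topology=(("A", "B"), ("C", "D")),
        root_length=356,
        substitutions_per_branch={"A+B": 60, "C+D": 60, "A": 5, "B": 5, "C": 5, "D": 5},
        rng_seed=7,
    )
    aln, truth = evolve_family(config)
    return aln, truth


@pytest.fixture
def paired_family_encoded(paired_family):
    aln, _ = paired_family
    return encode_alignment(list(aln))
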