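import numpy as np
import pytest

from venomscan.codonmodel import BranchSiteParams, CodonFrequencies
from venomscan.seqio import CodonAlignment, parse_labeled_tree


@pytest.fixture
def rng():
    return np.random.default_rng(2011)


@pytest.fixture
def tiny_tree():
    """Three leaves, foreground on the AB-clade stem."""
    return parse_labeled_tree("((A:0.1,B:0.2)#1:0.05,C:0.3);")


@pytest.fixture
def small_tree():
    """Six leaves, a two-leaf foreground clade (stem and terminals)."""
    return parse_labeled_tree(
        "(((A#1:0.2,B#1:0.15)#1:0.1,(C:0.2,D:0.25):0.1):0.05,(E:0.3,F:0.2):0.05);"
    )


@pytest.fixture
def tiny_alignment():
    return CodonAlignment(
        taxa=("A", "B", "C"),
        sequences=("TTTAAAGGC", "TTCAAAGGT", "TTTAACGGC"),
    )


@pytest.fixture
def default_params():
    return BranchSiteParams(kappa=2.0, p0=0.6, p1=0.2, omega0=0.05, omega2=4.0)


@pytest.fixture
def uniform_freqs():
    return CodonFrequencies.uniform()
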