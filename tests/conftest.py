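import numpy as np
import pytest

from hdnacap import (
    LandscapeWeights,
    MeiosisParams,
    build_landscape,
    generate_population,
)
from hdnacap.synthetic import make_demo_chromosome, make_demo_panel, make_demo_tracks


@pytest.fixture(scope="session")
def chrom():
    return make_demo_chromosome()


@pytest.fixture(scope="session")
def tracks(chrom):
    return make_demo_tracks(chrom, rng=11)


@pytest.fixture(scope="session")
def panel(chrom):
    return make_demo_panel(chrom, n_markers=79, rng=11)


@pytest.fixture(scope="session")
def landscape(chrom, tracks):
    return build_landscape(list(tracks.values()), chrom, LandscapeWeights())


@pytest.fixture(scope="session")
def small_population(chrom, panel, landscape):
    """83 triploids (the larger study population size), default parameters."""
    table, truth = generate_population(
        MeiosisParams(), landscape, panel, chrom, n_individuals=83,
        rng=np.random.default_rng(5),
    )
    return table, truth
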