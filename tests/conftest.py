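import numpy as np
import pytest

from dcquant import movie_io, synthetic_embryo as se


@pytest.fixture(scope="session")
def sheet_cache():
    """Lazily rendered AS sheets keyed by genotype (seed 1, noise off)."""
    cache = {}

    def get(name: str):
        if name not in cache:
            preset = se.make_preset(name)
            movie, truth = se.simulate_as_sheet(preset, seed=1, noise=False)
            tracks = movie_io.link_tracks(movie)
            cache[name] = (preset, movie, truth, tracks)
        return cache[name]

    return get


@pytest.fixture(scope="session")
def wt_sheet(sheet_cache):
    return sheet_cache("WT")


@pytest.fixture(scope="session")
def wt_hole():
    return se.simulate_closure(se.make_preset("WT"), seed=1, noise=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(20220901)
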