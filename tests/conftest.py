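import numpy as np
import pytest

import nucadapt as na


@pytest.fixture(scope="session")
def layout_params() -> na.LayoutParams:
    return na.LayoutParams()


@pytest.fixture(scope="session")
def small_domain_pair(layout_params):
    """4 + 4 images of the default source/target styles (session-cached)."""
    return na.make_domain_datasets(
        layout_params,
        na.default_source_style(),
        na.default_target_style(),
        4,
        4,
        seed=101,
    )


@pytest.fixture(scope="session")
def source_image(small_domain_pair):
    return small_domain_pair[0][0]


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def well_separated_layout(seed: int, n: int = 4, dims: int = 128) -> list:
    """Random layouts whose pairwise spacing exceeds twice the proximity-bump
    radius, so target-map peaks cannot interact."""
    params = na.LayoutParams(
        height=dims,
        width=dims,
        n_ipt=max(0, n - 3),
        n_int=2,
        n_nt=1,
        min_separation=26.0,
    )
    return na.sample_layout(params, seed)
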