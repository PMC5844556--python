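import numpy as np
import pytest

from cbscaffold import (
    LigandParams,
    ReferenceMatcher,
    pseudo_experimental_barcode,
    random_genome,
)
from cbscaffold.io import default_netropsin_table


@pytest.fixture(scope="session")
def params() -> LigandParams:
    return LigandParams(netropsin_constants=default_netropsin_table())


@pytest.fixture(scope="session")
def small_genome(params):
    return random_genome(60_000, circular=True, seed=101, id="smallref")


@pytest.fixture(scope="session")
def small_reference(small_genome, params):
    """120-px pseudo-experimental reference barcode at moderate noise."""
    return pseudo_experimental_barcode(
        small_genome, params, sigma_bp=1000, bp_per_px=500, noise_sd=0.3, seed=7
    )


@pytest.fixture(scope="session")
def small_matcher(small_reference):
    return ReferenceMatcher(small_reference)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
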