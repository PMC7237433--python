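import numpy as np
import pytest
from hypothesis import settings

from sporedyn.reduction import normalize_to_vanadium, subtract_empty_cell
from sporedyn.synthetic import (MSDLaw, SampleSpec, germinating_spec,
                                simulate_scan_triplet, wildtype_spec)

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")


def reduce_triplet(triplet):
    """Standard reduction chain: empty-cell subtraction then vanadium division."""
    corrected = subtract_empty_cell(triplet.sample, triplet.empty,
                                    triplet.truth["coefficients"])
    return normalize_to_vanadium(corrected, triplet.vanadium)


def single_population_spec(u0=0.5, slope=0.0069, seed=0, label="single", **overrides):
    """p = 0 sample whose fitted MSD should reproduce the law exactly."""
    law = MSDLaw(u0=u0, slope=slope, T_ref=280.0)
    overrides.setdefault("flat_background", 0.0)
    return SampleSpec(population_small=law, population_large=law,
                      fraction_large=0.0, seed=seed, label=label, **overrides)


@pytest.fixture(scope="session")
def wt_noiseless():
    return simulate_scan_triplet(wildtype_spec(seed=11), noise=False)


@pytest.fixture(scope="session")
def germinating_noiseless():
    return simulate_scan_triplet(germinating_spec(seed=12), noise=False)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
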