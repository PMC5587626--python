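import numpy as np
import pytest

from spingroup import (
    NoiseModel,
    PeakList,
    Peak,
    add_noise,
    builtin_description,
    ideal_peaklist,
    synth_assignments,
)
from spingroup.simulator import sigmas_for


@pytest.fixture(scope="session")
def hnco():
    return builtin_description("HNcoCACB")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_peaklist(shifts, comparable_dims=None, labels=None, truth=None, name="toy"):
    """Build a PeakList from a nested shift list."""
    ndim = len(shifts[0]) if shifts else 2
    peaks = [
        Peak(
            k,
            tuple(s),
            None if labels is None else labels[k],
            None if truth is None else truth[k],
        )
        for k, s in enumerate(shifts)
    ]
    return PeakList(
        name=name,
        dim_labels=tuple(f"w{i+1}" for i in range(ndim)),
        peaks=peaks,
        comparable_dims=tuple(comparable_dims) if comparable_dims else tuple(range(ndim)),
    )


def simulated_list(
    n_res=80,
    table_seed=11,
    noise_seed=12,
    sigma_h=0.001,
    sigma_c=0.01,
    sigma_n=0.01,
    fraction_high=0.0,
    multiplier=5.0,
    spec=None,
):
    """One noisy simulated HN(CO)CACB peak list with truth labels."""
    spec = spec or builtin_description("HNcoCACB")
    table = synth_assignments(n_res, seed=table_seed)
    ideal = ideal_peaklist(table, spec)
    nm = NoiseModel(
        sigmas_for(spec, sigma_h, sigma_c, sigma_n),
        fraction_high=fraction_high,
        multiplier=multiplier,
        seed=noise_seed,
    )
    return add_noise(ideal, nm)
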