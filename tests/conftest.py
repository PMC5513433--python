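import numpy as np
import pytest

from thermolocus import benchmark, predict
from thermolocus.sites import BindingSite, SiteWeightMatrix


@pytest.fixture(scope="session")
def bench():
    """The standing two-enhancer benchmark: (spec, bundle, params)."""
    return benchmark(seed=0)


@pytest.fixture(scope="session")
def bench_output(bench):
    _, bundle, params = bench
    return predict(bundle.seq, bundle.pwms, params, bundle.profiles)


def random_site_instance(rng, n, n_positions=3, coop_frac=0.5, span=200,
                         zero_frac=0.1):
    """A random occupancy instance: overlapping stranded sites of a
    cooperative TF 'C' and an inert TF 'X', with gamma-distributed weights
    (a fraction zeroed to exercise vanishing concentrations)."""
    starts = np.sort(rng.integers(0, span, n))
    sites = []
    for i, s in enumerate(starts):
        length = int(rng.integers(6, 12))
        tf = "C" if rng.random() < coop_frac else "X"
        strand = "+" if rng.random() < 0.5 else "-"
        sites.append(BindingSite(i, tf, int(s), int(s) + length, strand, 1.0))
    q = rng.gamma(1.0, 2.0, size=(n, n_positions))
    q[rng.random((n, n_positions)) < zero_frac] = 0.0
    return sites, SiteWeightMatrix(tuple(sites), q)
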