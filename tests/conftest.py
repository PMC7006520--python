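import numpy as np
import pytest

import seawhip as sw


@pytest.fixture(scope="session")
def reader_pairs_102():
    """102 paired reads: 84 equal, 10 with reader 2 one year older, 8 with
    reader 2 one year younger (off-diagonal sums A=10, B=8), at ages
    spread over the 3-12 y range so APE/ACV are meaningful."""
    base = [3 + (i % 10) for i in range(102)]
    pairs = []
    for i, a in enumerate(base):
        if i < 84:
            pairs.append((a, a))
        elif i < 94:
            pairs.append((a, a + 1))
        else:
            pairs.append((a + 1, a))
    return pairs


@pytest.fixture(scope="session")
def vbgf_truth():
    return sw.VBGFParams(86.1, 0.14, 1.44)


@pytest.fixture(scope="session")
def noisy_population():
    """Default synthetic study population (102 aged + 119 in-situ)."""
    return sw.gen_population(sw.PopulationGenSpec(seed=42))


def draw_age_length(rng, n, params, noise_sd=5.0):
    """Ages from the default age distribution, lengths from the growth
    curve plus Gaussian noise (independent oracle-side sampler)."""
    ages = np.array(list(sw.DEFAULT_AGE_DISTRIBUTION))
    probs = np.array(list(sw.DEFAULT_AGE_DISTRIBUTION.values()))
    a = rng.choice(ages, p=probs, size=n).astype(float)
    length = sw.predict_length(params, a) + rng.normal(0.0, noise_sd, size=n)
    return a, length
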