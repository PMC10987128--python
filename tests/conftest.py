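import numpy as np
import pytest

from meltshift import DEFAULT_GRADIENT, MeltProfile, sigmoid
from meltshift.synthetic import _solve_curve


@pytest.fixture
def gradient():
    return DEFAULT_GRADIENT


@pytest.fixture
def rng():
    return np.random.default_rng(20231001)


def make_profile(a, b, p, gradient=DEFAULT_GRADIENT, protein_id="PX",
                 condition="vehicle", replicate=1, noise_sd=0.0, rng=None):
    """Noise-free (or lognormal-noised) profile from exact sigmoid parameters."""
    t = np.asarray(gradient.temperatures)
    y = sigmoid(t, a, b, p)
    if noise_sd > 0:
        y = y * np.exp(rng.normal(0.0, noise_sd, size=t.size))
        y = y / y[0]
    return MeltProfile(protein_id, condition, replicate, tuple(float(v) for v in y))


def random_admissible_params(rng, n, tm_range=(38.0, 64.0), slope_range=(0.03, 0.4),
                             plateau_range=(0.0, 0.44)):
    """Random (a, b, p) triples inside the fitting bounds, via the
    (Tm, slope, plateau) parameterization."""
    out = []
    while len(out) < n:
        tm = rng.uniform(*tm_range)
        s = rng.uniform(*slope_range)
        p = rng.uniform(*plateau_range)
        try:
            params = _solve_curve(tm, s, p)
        except Exception:
            continue
        if 100 <= params.a <= 20000 and 1 <= params.b <= 400:
            out.append(params)
    return out
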