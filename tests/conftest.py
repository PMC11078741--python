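"""Shared fixtures: small synthetic bundles and hand-built experiments."""

import numpy as np
import pandas as pd
import pytest

from netomics import synthetic_data as sd
from netomics.types import CountsExperiment


def make_experiment(counts: np.ndarray, groups, treatments=None,
                    tissues=None, subjects=None) -> CountsExperiment:
    """Build a CountsExperiment from a raw matrix and design lists."""
    n = counts.shape[1]
    samples = [f"s{i:02d}" for i in range(n)]
    treatments = treatments or ["Li-"] * n
    tissues = tissues or ["fibroblast"] * n
    subjects = subjects or samples
    design = pd.DataFrame(
        {
            "group": groups,
            "treatment": treatments,
            "tissue": tissues,
            "subject": subjects,
            "clone": [f"{s}.c1" for s in subjects],
        },
        index=pd.Index(samples, name="sample"),
    )
    frame = pd.DataFrame(counts,
                         index=pd.Index([f"g{i:04d}" for i in
                                         range(counts.shape[0])], name="gene"),
                         columns=samples)
    return CountsExperiment(counts=frame, design=design)


def nb_counts(rng, mean, dispersion, size):
    """Draw NB counts (gamma-Poisson) with var = mu + dispersion * mu^2."""
    r = 1.0 / dispersion
    mean = np.asarray(mean, float)
    lam = rng.gamma(shape=r, scale=np.tile(mean[:, None], (1, size)) / r)
    return rng.poisson(lam)


@pytest.fixture(scope="session")
def small_params():
    return sd.preset("small")


@pytest.fixture(scope="session")
def small_bundle(small_params):
    """One deterministic reduced-scale fixture shared across tests."""
    return sd.simulate_bundle(seed=123, params=small_params)


@pytest.fixture(scope="session")
def small_fixture_dir(small_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    sd.write_fixture(small_bundle, out, force=True)
    return out
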