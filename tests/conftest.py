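import numpy as np
import pytest

from spectra import models
from spectra.synth import six_factor_preset, simulate_dataset
from spectra.tetra import correlation_matrix

PRESET_SEED = 11


@pytest.fixture(scope="session")
def preset_cfg_20k():
    return six_factor_preset(n_persons=20_000, seed=PRESET_SEED)


@pytest.fixture(scope="session")
def preset_data_20k(preset_cfg_20k):
    """One shared n = 20,000 preset cohort: (matrix, events, cmap,
    correlates, truth)."""
    return simulate_dataset(preset_cfg_20k)


@pytest.fixture(scope="session")
def preset_matrix_20k(preset_data_20k):
    return preset_data_20k[0]


@pytest.fixture(scope="session")
def preset_truth_20k(preset_data_20k):
    return preset_data_20k[4]


@pytest.fixture(scope="session")
def preset_R_20k(preset_matrix_20k):
    return correlation_matrix(preset_matrix_20k)


@pytest.fixture(scope="session")
def truth_spec(preset_cfg_20k):
    """ModelSpec matching the generating six-factor structure."""
    return models.truth_model(preset_cfg_20k)


@pytest.fixture(scope="session")
def preset_fit_20k(preset_R_20k, preset_matrix_20k, truth_spec):
    from spectra.cfa import fit

    return fit(preset_R_20k, preset_matrix_20k.n_persons, truth_spec)


@pytest.fixture(scope="session")
def small_data_4k():
    """Cheaper preset cohort for stochastic smoke checks."""
    cfg = six_factor_preset(n_persons=4_000, seed=7)
    return simulate_dataset(cfg)


def loading_errors(fit_result, cfg):
    """Signed estimation errors over all nonzero generating loadings."""
    errs = []
    for j, lab in enumerate(cfg.labels):
        for ki, fn in enumerate(cfg.factor_names):
            if cfg.loadings[j, ki] != 0:
                errs.append(fit_result.loadings.at[lab, fn]
                            - cfg.loadings[j, ki])
    return np.asarray(errs)
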