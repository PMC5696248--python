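import numpy as np
import pandas as pd
import pytest

from mrmpanel import evaluation, panels, quantitation, synthetic


@pytest.fixture(scope="session")
def default_cohort():
    """Study-sized cohort (1008 samples) with the default marker set."""
    cfg = synthetic.default_cohort_config(seed=42)
    meta, gt = synthetic.generate_cohort(cfg)
    records = synthetic.generate_transition_data(meta, cfg, gt)
    return cfg, meta, gt, records


@pytest.fixture(scope="session")
def default_quant(default_cohort):
    _, _, _, records = default_cohort
    return quantitation.quantify(records)


@pytest.fixture(scope="session")
def default_features(default_cohort, default_quant):
    _, meta, _, _ = default_cohort
    qmat = quantitation.quant_matrix(default_quant)
    return panels.build_feature_matrix(qmat, meta)


@pytest.fixture(scope="session")
def default_split(default_cohort):
    _, meta, _, _ = default_cohort
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return evaluation.split_train_test(meta, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
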