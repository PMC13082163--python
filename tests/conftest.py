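import warnings

import numpy as np
import pandas as pd
import pytest

import pvtuning as pv


@pytest.fixture(scope="session")
def directions24() -> np.ndarray:
    return np.arange(24) * 15.0


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-unit PVA cohort with ground truth (shared, read-only)."""
    cfg = pv.CohortConfig(n_units=30)
    trials, units = pv.generate_cohort(cfg, seed=101)
    return cfg, trials, units


@pytest.fixture(scope="session")
def analyzed_small_cohort(small_cohort):
    cfg, trials, units = small_cohort
    layers = {u.unit_id: u.layer for u in units}
    sponts = {u.unit_id: u.spont_rate for u in units}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        analysis = pv.analyze_cohort(
            trials, cfg.manipulation, layers=layers, spont_rates=sponts
        )
    return cfg, units, analysis


def truth_frame(units) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"unit_id": u.unit_id, "true_class": u.effect_class, "layer": u.layer}
            for u in units
        ]
    )
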