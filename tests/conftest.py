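import numpy as np
import pandas as pd
import pytest

from phenolmm.simulate import SimulationTruth, generate_cohort, generate_monthly_panel


@pytest.fixture(scope="session")
def small_truth():
    """A 4-patient, few-month truth small enough for window-level tests."""
    return SimulationTruth(
        n_patients=4,
        followup_months_per_patient=[3, 2, 4, 3],
        seed=11,
        fixed_slopes={("acc_ste_wake_mean", "negative"): -0.8},
        random_slope_sd=0.2,
    )


@pytest.fixture(scope="session")
def small_bundle(small_truth):
    return generate_cohort(small_truth)


@pytest.fixture(scope="session")
def panel_null():
    """Monthly modelling table from a null truth (no planted slopes)."""
    return generate_monthly_panel(SimulationTruth(n_patients=38, seed=5))


def ri_dataset(seed=0, n_groups=12, n_per=8, beta=(2.0, 0.7), sd_b=1.5, sd_e=1.0):
    """Simple random-intercept dataset used across LMM tests."""
    rng = np.random.default_rng(seed)
    pid = np.repeat(np.arange(n_groups), n_per)
    x = rng.normal(size=n_groups * n_per)
    b = rng.normal(0, sd_b, n_groups)
    y = beta[0] + beta[1] * x + b[pid] + rng.normal(0, sd_e, n_groups * n_per)
    return pd.DataFrame(
        {
            "patient_id": pid,
            "month_index": np.tile(np.arange(n_per), n_groups),
            "x": x,
            "y": y,
        }
    )
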