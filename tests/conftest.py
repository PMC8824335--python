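import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import locpattern as lp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ideal_subject():
    cat = lp.make_category("Ideal", "Ideal")
    return lp.simulate_subject(cat, 15, 11, subject_code="IDEAL")


@pytest.fixture(scope="session")
def flat_subject():
    cat = lp.make_category("Flat", "Ideal")
    return lp.simulate_subject(cat, 15, 12, subject_code="FLAT")


@pytest.fixture(scope="session")
def cohort48():
    """48 simulated listeners cycling through the 20 stock categories, with
    matching synthetic demographics (session-scoped: several batteries reuse it)."""
    import pandas as pd

    cats = lp.stock_categories()
    rng = np.random.default_rng(2024)
    frames, fac_rows = [], []
    for i in range(48):
        cat = cats[i % len(cats)]
        code = f"C{i:03d}"
        subj = lp.simulate_subject(
            cat, 15, np.random.default_rng(rng.integers(2**63)), subject_code=code
        )
        frames.append(subj.dataset.trials)
        onset = rng.uniform(0, 5) if i < 16 else rng.uniform(6, 60)
        fac_rows.append(
            {"subject": code, "onset_age": onset,
             "testing_age": max(onset + 1, rng.uniform(18, 85))}
        )
    dataset = lp.LocalizationDataset(pd.concat(frames, ignore_index=True))
    factors = lp.derive_factors(pd.DataFrame(fac_rows))
    return dataset, factors
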