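import numpy as np
import pandas as pd
import pytest

from equipain.config import ObserverParams, StudyConfig, TrialSpec
from equipain.pipeline import make_fixtures


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Small deterministic fixture study shared across the suite."""
    out = tmp_path_factory.mktemp("fixture_study")
    make_fixtures(out, seed=0)
    return out


@pytest.fixture(scope="session")
def default_config():
    return StudyConfig(seed=11)


def simulate_model_frame(rng, n_horses=8, per_horse=50, phi=0.0, sigma2_horse=0.0,
                         slope=0.1, intercept=2.0, timing_effect=0.5,
                         noise_sd=1.0, curve=None):
    """Longitudinal score~TAS data with known linear (or custom) truth."""
    rows = []
    for h in range(n_horses):
        b = rng.normal(0.0, np.sqrt(sigma2_horse)) if sigma2_horse > 0 else 0.0
        e = np.empty(per_horse)
        e[0] = rng.normal(0.0, noise_sd)
        for j in range(1, per_horse):
            innov_sd = noise_sd * np.sqrt(1.0 - phi ** 2)
            e[j] = phi * e[j - 1] + rng.normal(0.0, innov_sd)
        tas = rng.uniform(0.0, 80.0, per_horse)
        timing = rng.choice(["before_gait", "after_gait"], per_horse)
        f = curve(tas) if curve is not None else slope * tas
        y = intercept + f + timing_effect * (timing == "before_gait") + b + e
        for j in range(per_horse):
            rows.append((f"H{h:02d}", j * 100.0 / per_horse, tas[j], timing[j], y[j]))
    return pd.DataFrame(
        rows, columns=["horse", "prop_time_pct", "tas_mm", "timing", "total"])
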