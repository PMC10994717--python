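import numpy as np
import pandas as pd
import pytest

from trajconsensus.io_model import LongitudinalDataset, VariableSpec
from trajconsensus.simulate import SimulationConfig, simulate_longitudinal_mixed


@pytest.fixture
def tiny_mixed_frame() -> pd.DataFrame:
    """2 subjects x 2 visits, one continuous and one binary variable."""
    return pd.DataFrame(
        {
            "pid": ["a", "a", "b", "b"],
            "visit": [0, 1, 0, 1],
            "score": [1.2, 1.5, 0.3, 0.1],
            "flag": ["yes", "no", "no", "no"],
        }
    )


@pytest.fixture
def tiny_dataset(tiny_mixed_frame) -> LongitudinalDataset:
    spec = [
        VariableSpec("score", "continuous"),
        VariableSpec("flag", "categorical", ("no", "yes")),
    ]
    return LongitudinalDataset.from_frame(tiny_mixed_frame, "pid", "visit", spec)


@pytest.fixture
def mixed_rows() -> pd.DataFrame:
    """Cross-sectional mixed rows: 3 continuous + 1 three-level categorical."""
    rng = np.random.default_rng(42)
    n = 40
    return pd.DataFrame(
        {
            "x1": rng.normal(size=n),
            "x2": rng.normal(2.0, 3.0, size=n),
            "x3": rng.uniform(-1, 1, size=n),
            "c1": rng.choice(["lo", "mid", "hi"], size=n),
        }
    )


def make_two_group_scores(
    n_subjects: int = 20,
    n_visits: int = 4,
    slope: float = 2.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    n_responses: int = 1,
) -> tuple[LongitudinalDataset, np.ndarray]:
    """Continuous-response fixture: half the subjects follow +slope*t, half
    -slope*t, with small Gaussian noise. Returns dataset and true labels."""
    rng = np.random.default_rng(seed)
    times = np.arange(n_visits, dtype=float)
    labels = np.array([0] * (n_subjects // 2) + [1] * (n_subjects - n_subjects // 2))
    ids = [f"P{i:03d}" for i in range(n_subjects)]
    rows = {
        "subject_id": np.repeat(ids, n_visits),
        "time": np.tile(times, n_subjects),
    }
    signs = np.where(labels == 0, 1.0, -1.0)
    for j in range(n_responses):
        y = (signs[:, None] * slope * times[None, :]).ravel()
        rows[f"y{j + 1}"] = y + rng.normal(0, noise_sd, size=n_subjects * n_visits)
    frame = pd.DataFrame(rows)
    specs = tuple(VariableSpec(f"y{j + 1}", "continuous") for j in range(n_responses))
    ds = LongitudinalDataset(frame, "subject_id", "time", specs)
    return ds, labels + 1


@pytest.fixture
def two_group_scores():
    return make_two_group_scores()


@pytest.fixture(scope="session")
def simulated_two_group():
    """Default-config two-group simulation shared across tests."""
    cfg = SimulationConfig(n_subjects=60, n_groups=2, seed=123)
    ds, labels = simulate_longitudinal_mixed(cfg)
    return cfg, ds, labels
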