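import itertools

import numpy as np
import pandas as pd
import pytest

from corticoflow.datatypes import Condition, EpochedRoiSeries, GroundTruthNetwork, Parcellation
from corticoflow.synthetic import simulate_var


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def chain_network(strength: float = 0.35, self_coupling: float = 0.5) -> GroundTruthNetwork:
    """3-ROI directed chain A -> B -> C with stable AR(1) self-coupling."""
    coup = np.zeros((3, 3, 1))
    coup[1, 0, 0] = strength
    coup[2, 1, 0] = strength
    for i in range(3):
        coup[i, i, 0] = self_coupling
    return GroundTruthNetwork(coupling=coup, noise_sd=np.ones(3))


def diagonal_network(n_rois: int, self_coupling: float = 0.5) -> GroundTruthNetwork:
    """Zero cross-coupling: independent AR(1) ROIs (the null network)."""
    coup = np.zeros((n_rois, n_rois, 1))
    for i in range(n_rois):
        coup[i, i, 0] = self_coupling
    return GroundTruthNetwork(coupling=coup, noise_sd=np.ones(n_rois))


def toy_series(values: np.ndarray, fs: float = 1000.0, t0: float = 0.0) -> EpochedRoiSeries:
    values = np.asarray(values, dtype=float)
    return EpochedRoiSeries(
        values=values,
        sampling_rate=fs,
        t0=t0,
        parcellation=Parcellation.generic(values.shape[1]),
    )


def null_nr_table(seed: int, n_participants: int = 28) -> pd.DataFrame:
    """NR table with participant intercepts and iid noise, no condition effects."""
    gen = np.random.default_rng(seed)
    rows = []
    for s in range(n_participants):
        icept = gen.normal(0, 0.5)
        for a, c, m in itertools.product(
            ("active", "passive"), ("intensity", "spectral"), ("looming", "receding")
        ):
            rows.append(
                {
                    "participant": f"s{s:02d}",
                    "attention": a,
                    "cue": c,
                    "motion": m,
                    "nr": icept + gen.normal(),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def ar1_block(rng):
    """Stationary 4-ROI AR(1) block, 6 trials x 200 samples."""
    return simulate_var(diagonal_network(4), n_samples=200, n_trials=6, seed=777)


@pytest.fixture
def cosine_dataset():
    """Dataset whose every series is a period-12 cosine (ACF minimum at 6)."""
    from corticoflow.datatypes import SyntheticDataset

    parc = Parcellation.generic(3)
    t = np.arange(120)
    base = np.cos(2 * np.pi * t / 12)
    rng = np.random.default_rng(0)
    blocks = {}
    for pid in ("sub01", "sub02"):
        for cond in (
            Condition("active", "intensity", "looming"),
            Condition("active", "intensity", "receding"),
        ):
            phases = rng.uniform(0, 2 * np.pi, size=(2, 3, 1))
            vals = np.cos(2 * np.pi * t[None, None, :] / 12 + phases)
            blocks[(pid, cond)] = EpochedRoiSeries(
                values=vals, sampling_rate=1000.0, t0=0.0, parcellation=parc,
                condition=cond, participant_id=pid,
            )
    return SyntheticDataset(blocks=blocks, truth={}, parcellation=parc,
                            sampling_rate=1000.0, seed=0)
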