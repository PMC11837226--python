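import numpy as np
import pytest

from flarekit import DyadSimConfig, simulate_dyad
from flarekit.kinematics import KeypointTable
from flarekit.simulate import render_keypoints


@pytest.fixture(scope="session")
def dyad_trial():
    """Medium dyad simulation reused across modules (2 min, equal dwells)."""
    return simulate_dyad(DyadSimConfig(duration=120.0, dwell_means=(2, 2, 2, 2),
                                       seed=11))


@pytest.fixture(scope="session")
def rendered_table(dyad_trial):
    agent = dyad_trial.agents[0]
    kp = render_keypoints(agent)
    return KeypointTable(data=kp, frame_rate=40.0, px_per_cm=20.0)


def make_separable_records(n_records=10, n_frames=4000, noise=0.12, seed0=0):
    """Three-class labels in random segments; channel 0 is a noisy copy of
    the label, the other two channels are pure noise."""
    records = []
    for s in range(seed0, seed0 + n_records):
        r = np.random.default_rng(s)
        labels = np.zeros(n_frames, dtype=int)
        t = 0
        while t < n_frames:
            d = int(r.exponential(60)) + 20
            labels[t:t + d] = r.integers(0, 3)
            t += d
        feats = np.column_stack([
            labels + r.normal(0.0, noise, n_frames),
            r.normal(0.0, 1.0, n_frames),
            r.normal(0.0, 1.0, n_frames),
        ])
        records.append((feats, labels))
    return records
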