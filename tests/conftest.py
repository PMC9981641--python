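import numpy as np
import pytest

from emabayes import EmaDataset, EmaFrame, EmaModel, EmaRecord
from emabayes.simulate import recovery_scenario, simulate_dataset


@pytest.fixture(scope="session")
def toy_frame() -> EmaFrame:
    """Two phases, 2x3 situation dimensions (K=6), one 5-level attribute."""
    return EmaFrame(
        phases=["before", "after"],
        situation_dims={
            "location": ["indoors", "outdoors"],
            "noisiness": ["quiet", "moderate", "loud"],
        },
        attributes={"quality": ["vbad", "bad", "ok", "good", "vgood"]},
        groups=["g1", "g2"],
    )


def _rec(frame, pid, group, phase, sit, rating=None):
    return EmaRecord.validate(
        frame, pid, group, phase, sit, {"quality": rating}
    )


@pytest.fixture(scope="session")
def toy_dataset(toy_frame) -> EmaDataset:
    f = toy_frame
    recs = [
        _rec(f, "alice", "g1", "before", ("indoors", "quiet"), 3),
        _rec(f, "alice", "g1", "before", ("indoors", "loud"), 1),
        _rec(f, "alice", "g1", "after", ("outdoors", "moderate"), 5),
        _rec(f, "alice", "g1", "after", ("indoors", "quiet"), None),
        _rec(f, "bob", "g2", "before", ("outdoors", "loud"), 2),
        _rec(f, "bob", "g2", "after", ("outdoors", "loud"), 4),
        _rec(f, "bob", "g2", "after", ("indoors", "moderate"), None),
    ]
    return EmaDataset(f, recs)


@pytest.fixture(scope="session")
def recovery_truth():
    return recovery_scenario()


@pytest.fixture(scope="session")
def recovery_fit(recovery_truth):
    """One moderately sized fitted model, shared across test modules."""
    ds = simulate_dataset(recovery_truth, N=12, seed=7)
    model = EmaModel(ds, effects=recovery_truth.effects)
    res = model.fit(
        M_max=5, n_chains=2, n_kept=40, n_warmup=60, max_iter=10, seed=7
    )
    return res


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
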