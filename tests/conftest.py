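import numpy as np
import pytest

from mimicry.ctrnn import CTRNNParams
from mimicry.trial import TrialConfig, TrialRecord


@pytest.fixture
def zero_params() -> CTRNNParams:
    """8-neuron network with no coupling: every state decays to 0."""
    n = 8
    return CTRNNParams(tau=np.ones(n), w=np.zeros((n, n)), theta=np.zeros(n),
                       r=1.0, e=np.zeros(3))


@pytest.fixture
def inert_params(zero_params) -> CTRNNParams:
    """Agents whose effector gains are 0: they never move or click."""
    return zero_params


@pytest.fixture
def random_params() -> CTRNNParams:
    """A fixed arbitrary decoded-range controller for generic dynamics tests."""
    rng = np.random.default_rng(42)
    n = 8
    return CTRNNParams(
        tau=rng.uniform(1, 30, n),
        w=rng.uniform(-8, 8, (n, n)),
        theta=rng.uniform(-8, 8, n),
        r=rng.uniform(0, 10),
        e=rng.uniform(0, 1, 3),
    )


def make_record(
    d1,
    d2,
    rf1=None,
    rf2=None,
    contacts=None,
    outputs=None,
    clicks=None,
    config=None,
) -> TrialRecord:
    """Assemble a synthetic TrialRecord from hand-built series (tests only)."""
    d1 = np.asarray(d1, dtype=float)
    steps = d1.shape[0]
    d2 = np.asarray(d2, dtype=float)
    rf1 = np.zeros(steps) if rf1 is None else np.asarray(rf1, dtype=float)
    rf2 = np.zeros(steps) if rf2 is None else np.asarray(rf2, dtype=float)
    contacts = (
        np.zeros((steps, 2), dtype=np.int8) if contacts is None else np.asarray(contacts, dtype=np.int8)
    )
    outputs = np.full((steps, 2, 8), 0.5) if outputs is None else np.asarray(outputs, dtype=float)
    clicks = (
        np.zeros((steps, 2, 2), dtype=np.int8) if clicks is None else np.asarray(clicks, dtype=np.int8)
    )
    cfg = config or TrialConfig(steps=steps)
    return TrialRecord(
        config=cfg,
        u1=0.0,
        u2=0.0,
        rf=np.column_stack([rf1, rf2]),
        d=np.column_stack([d1, d2]),
        contacts=contacts,
        outputs=outputs,
        clicks=clicks,
    )
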