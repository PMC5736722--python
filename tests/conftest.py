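import numpy as np
import pytest

import arni


@pytest.fixture(scope="session")
def phase_spec():
    return arni.random_indegree_network(N=10, n_in=3, seed=5)


@pytest.fixture(scope="session")
def phase_ts(phase_spec):
    cfg = arni.SimConfig(dt=0.05, m=10, S=60, seed=5)
    return arni.simulate_phase(phase_spec, cfg)


@pytest.fixture(scope="session")
def phase_ds(phase_ts):
    return arni.estimate_derivatives(phase_ts, "forward2")


def make_ts(X, dt=1.0, seg_len=None):
    """Wrap a plain (M, D) array as a single- or multi-segment TimeSeriesSet."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if seg_len is None:
        segments = [X]
    else:
        segments = [X[i:i + seg_len] for i in range(0, X.shape[0], seg_len)]
    layout = [[i] for i in range(X.shape[1])]
    return arni.TimeSeriesSet(segments=segments, dt=dt, unit_layout=layout)
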