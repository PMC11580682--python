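import numpy as np
import pytest

from tandemhmm.model import ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_params():
    """Small model with indel machinery, cheap enough for naive engines."""
    return ModelParams(max_period=3, n_insert=1, n_delete=1)


def random_small_params(rng, k_max=2, indel_max=1):
    """Random parameter draw for oracle comparisons on tiny models."""
    k = int(rng.integers(1, k_max + 1))
    ni = int(rng.integers(0, indel_max + 1))
    bg = rng.dirichlet([5.0, 5.0, 5.0, 5.0])
    return ModelParams(
        max_period=k,
        match_prob=float(rng.uniform(0.55, 0.9)),
        decay=float(rng.uniform(0.5, 0.99)),
        n_insert=ni, n_delete=ni,
        background=tuple(bg),
        repeat_entry=float(rng.uniform(0.005, 0.3)),
        repeat_exit=float(rng.uniform(0.02, 0.2)),
        indel_open=float(rng.uniform(0.01, 0.15)),
        indel_extend=float(rng.uniform(0.1, 0.4)),
    )


def reference_path_arrays(emitted, silent_events, topo):
    """Project a naive-engine path onto the arrays the fast engine emits."""
    kmap = {"nonrepetitive": 0, "repetitive": 1, "insert": 2, "offset": 3}
    st = topo.states
    n = len(emitted)
    kind = np.zeros(n, dtype=np.int8)
    per = np.zeros(n, dtype=np.int32)
    look = np.zeros(n, dtype=np.int32)
    for i, v in enumerate(emitted):
        s = st[v]
        kind[i] = kmap[s.kind]
        per[i] = s.machinery_period
        look[i] = s.look_back
    events: dict[int, int] = {}
    for (t, v) in silent_events:
        events[t] = max(events.get(t, 0), st[v].depth)
    return kind, per, look, sorted(events.items())
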