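import numpy as np
import pytest

from oscseq.core import ModelParams, TargetMap


@pytest.fixture
def unimodal_targets():
    return TargetMap.unimodal()


@pytest.fixture
def quiet_params():
    """Visual parameters with the phase jitter switched off."""
    return ModelParams(noise_std=0.0)


@pytest.fixture
def default_params():
    return ModelParams()


def drive_single(stream, params, targets, seed):
    """Drive one ensemble through a symbol list; returns (state, errors,
    reset counts, state-label history)."""
    from oscseq.core import init_ensemble, step

    rng = np.random.default_rng(seed)
    state = init_ensemble(params, rng=rng)
    errors, resets, states = [], [], []
    for sym in stream:
        state, res = step(state, int(sym), targets, params, rng)
        errors.append(res.error)
        resets.append(int(res.resets.sum()))
        states.append(res.states)
    return state, np.asarray(errors), np.asarray(resets), states
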