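import numpy as np
import pytest

from brainpatch.data_io import session_zscore
from brainpatch.model import ModelConfig, ModelState
from brainpatch.synth import SynthConfig, generate, worked_fixture

TINY = ModelConfig(
    patch_len=8, d_model=16, n_blocks=2, n_heads=2, ffn_hidden=16,
    p_drop=0.0, n_classes=3,
)


@pytest.fixture
def tiny_state() -> ModelState:
    """Small model with a 3-channel, 3-slot montage registered."""
    state = ModelState(TINY, seed=0)
    state.register_montage(("C3", "CZ", "C4"), 3)
    return state


@pytest.fixture(scope="session")
def fixture_trials():
    """The deterministic 12-trial worked dataset, session z-scored."""
    zs, _ = session_zscore(worked_fixture())
    return zs


def make_sessions(effect: float, trials_per_class: int = 40, seed: int = 0,
                  sessions: int = 2, **kw):
    """Synthetic train/eval trial lists, each session z-scored separately."""
    cfg = SynthConfig(
        n_subjects=2, trials_per_class=trials_per_class, effect_size=effect,
        rng_seed=seed, sessions_per_subject=sessions, **kw,
    )
    out = {sid: session_zscore(s)[0] for sid, s in generate(cfg).items()}
    train = [t for sid, s in out.items() if sid.endswith("sess0") for t in s]
    evals = [t for sid, s in out.items() if not sid.endswith("sess0") for t in s]
    return train, evals
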