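import numpy as np
import pytest

from skywatch import bgsub, synth

SCENE_SEED = 7
SCENE_FRAMES = 120
WARMUP = 15


@pytest.fixture(scope="session")
def scene_pair():
    """Static and dynamic renderings of identical bird trajectories.

    The two configs differ only in background mode and share a seed, so the
    ground truth is the same; used by the background-subtraction comparison
    tests.  Returns {mode: (frames, gts)}.
    """
    out = {}
    for mode in ("static", "dynamic"):
        cfg = synth.klim_preset(
            n_frames=SCENE_FRAMES, seed=SCENE_SEED, background_mode=mode
        )
        frames, gts = synth.generate_sequence(cfg)
        out[mode] = (frames, gts)
    return out


@pytest.fixture(scope="session")
def scene_detections(scene_pair):
    """Background-subtraction detections for both scenes, default config."""
    return {
        mode: bgsub.detect_sequence(frames)
        for mode, (frames, gts) in scene_pair.items()
    }


@pytest.fixture(scope="session")
def klim_annotations():
    """A full-size Klim-like annotation set: 200 frames x 12 birds = 2400
    ground-truth boxes (annotation statistics only; rendering not needed by
    most consumers but comes from the same generator)."""
    cfg = synth.klim_preset(seed=11)
    _, gts = synth.generate_sequence(cfg)
    return gts


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
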