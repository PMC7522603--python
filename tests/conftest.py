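import numpy as np
import pytest

import virtualstain as vs


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_channel(rng, shape=(16, 16), bit_depth=8, label="x"):
    full = (1 << bit_depth) - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return vs.ChannelImage(rng.integers(0, full + 1, size=shape).astype(dtype),
                           bit_depth, channel_label=label)


def scene_pairs(coupling, n_scenes, seed0, input_channel="fibers",
                target_channel="puncta", image_shape=(96, 96), noise_sigma=0.01):
    """Fiber->puncta paired samples from synthetic scenes."""
    pairs = []
    for i in range(n_scenes):
        params = vs.SceneParams(image_shape=image_shape, n_cells=4,
                                puncta_coupling=coupling, noise_sigma=noise_sigma,
                                seed=seed0 + i)
        scene = vs.generate_scene(params)
        pairs.append(vs.PairedSample([scene[input_channel]], scene[target_channel]))
    return pairs


def crop_all(samples, patch_size, count, seed):
    spec = vs.PatchSpec(patch_size, count, seed)
    return [p for s in samples for p in vs.crop_patch_pairs(s, spec)]


# study-scale training configuration: depth-3 U-Net on 32-px patches with a
# step size suited to a few-hundred-step CPU budget
STUDY_GSPEC = dict(in_channels=1, depth=3, base_filters=16)
STUDY_DSPEC = dict(in_channels=2, base_filters=8)
STUDY_LR = 5e-3
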