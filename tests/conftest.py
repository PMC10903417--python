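import numpy as np
import pytest

from virtustain.phantom import (PhantomParams, render_brightfield,
                                render_fluorescence, sample_scene)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_field():
    """One rendered phantom field with ground truth, default parameters."""
    params = PhantomParams(seed=11)
    scene = sample_scene(params)
    fluor, gt = render_fluorescence(scene, params)
    stack = render_brightfield(scene, params)
    return {"params": params, "scene": scene, "fluor": fluor, "gt": gt,
            "stack": stack}


def toy_one_to_many(n_pairs: int = 32, size: int = 16, seed: int = 42):
    """A fixed input mapped to two equiprobable targets A and B.

    The targets are offset Gaussian blobs; their per-pixel mean is the
    MSE-optimal prediction and either blob is an L1/adversarial-optimal one.
    """
    rng = np.random.default_rng(seed)
    x = rng.random((1, size, size)).astype(np.float32)
    yy, xx = np.mgrid[0:size, 0:size]
    mid = size // 2
    a = (np.exp(-((yy - mid) ** 2 + (xx - mid // 2) ** 2) / 8) * 0.8
         + 0.1).astype(np.float32)[None]
    b = (np.exp(-((yy - mid) ** 2 + (xx - (mid + mid // 2)) ** 2) / 8) * 0.8
         + 0.1).astype(np.float32)[None]
    a3, b3 = np.repeat(a, 3, 0), np.repeat(b, 3, 0)
    train = [(x, a3) if i % 2 == 0 else (x, b3) for i in range(n_pairs)]
    val = [(x, a3), (x, b3)]
    return x, a3, b3, train, val


def make_phantom_pairs(n: int, seed0: int, params_fn):
    """Render n (stack, target) float pairs on the [0, 1] scale."""
    pairs = []
    for i in range(n):
        p = params_fn(seed0 + i)
        scene = sample_scene(p)
        fl, _ = render_fluorescence(scene, p)
        bf = render_brightfield(scene, p)
        pairs.append((bf.astype(np.float32) / 65535.0,
                      fl.astype(np.float32) / 65535.0))
    return pairs
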