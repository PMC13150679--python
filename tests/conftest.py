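import numpy as np
import pytest

from rbcq.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def sparse_scene():
    """20 cells, no overlap, half sickled."""
    spec = SceneSpec(
        n_cells=20, target_overlap_rate=0.0, sickled_fraction=0.5, seed=1
    )
    return spec, generate_scene(spec)


@pytest.fixture(scope="session")
def dense_scene():
    """50 cells at 0.5 overlap, half sickled."""
    spec = SceneSpec(
        n_cells=50, target_overlap_rate=0.5, sickled_fraction=0.5, seed=2
    )
    return spec, generate_scene(spec)


@pytest.fixture(scope="session")
def video_factory(tmp_path_factory):
    """Write a tiny multi-page TIFF 'video' and return its path.

    Default: 120 s at 4 fps -> 481 frames (frame 0 at t=0)."""
    root = tmp_path_factory.mktemp("videos")

    def make(name="vid.tif", n_frames=481, shape=(16, 16), seed=0):
        import tifffile

        rng = np.random.default_rng(seed)
        stack = rng.integers(0, 256, size=(n_frames, *shape), dtype=np.uint8)
        path = root / name
        tifffile.imwrite(path, stack)
        return path

    return make


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


@pytest.fixture(scope="session")
def dumbbell():
    """Two radius-10 discs with centers 16 px apart, merged into one region."""
    m1 = disc_mask((60, 80), (30, 32), 10)
    m2 = disc_mask((60, 80), (30, 48), 10)
    return m1, m2, m1 | m2
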