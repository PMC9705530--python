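import numpy as np
import pytest

from volca.components import ComponentSet
from volca.io import Movie4D, MovieMeta


@pytest.fixture
def meta20x() -> MovieMeta:
    """Acquisition geometry of the 20x recordings: (3, 1.3, 1.3) um voxels, 5 Hz."""
    return MovieMeta(voxel_size=(3.0, 1.3, 1.3), frame_interval=0.2,
                     plane_exposure=0.01, n_planes=20)


def gaussian_blob(shape, center, sigma):
    """Smooth 3D test volume with a single Gaussian blob."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, sigma))
    return np.exp(-r2 / 2.0)


def component_set_with_counts(voxel_counts, meta, t=20):
    """ComponentSet whose footprints have exactly the requested voxel counts."""
    nmax = max(voxel_counts)
    side = int(np.ceil(nmax ** (1 / 3))) + 2
    fps = []
    for n in voxel_counts:
        fp = np.zeros((side, side, side))
        fp.ravel()[:n] = 1.0
        fps.append(fp)
    fps = np.stack(fps)
    rng = np.random.default_rng(0)
    traces = rng.random((len(voxel_counts), t)) + 0.5
    return ComponentSet(footprints=fps, traces=traces, raw_traces=traces.copy(), meta=meta)


def component_set_with_traces(traces, meta):
    """ComponentSet with given traces and unit-voxel footprints."""
    traces = np.asarray(traces, dtype=float)
    n = len(traces)
    fps = np.zeros((n, 4, 4, n))
    for i in range(n):
        fps[i, 1, 1, i] = 1.0
    return ComponentSet(footprints=fps, traces=traces, raw_traces=traces.copy(), meta=meta)


@pytest.fixture
def small_movie(meta20x) -> Movie4D:
    """Seeded random nonnegative movie for contract tests."""
    rng = np.random.default_rng(7)
    return Movie4D(rng.random((10, 4, 8, 8)).astype(np.float32) + 0.5, meta20x)
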