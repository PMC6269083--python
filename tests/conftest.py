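import numpy as np
import pytest

import slidescope as s


@pytest.fixture(scope="session")
def he():
    return s.he_matrix()


@pytest.fixture(scope="session")
def lfb():
    return s.lfb_nfr_matrix()


@pytest.fixture(scope="session")
def small_grid():
    return s.TileGrid(2, 3, 1000, 800, overlap=0.05, pixel_size_um=0.54)


@pytest.fixture(scope="session")
def nuclei_tile(he):
    """400x400 px H&E-like tile at ~3000 nuclei/mm^2 with exact truth."""
    rgb, truth = s.render_nuclei_tile((400, 400), 0.54, 3000.0, seed=101)
    return rgb, truth


@pytest.fixture(scope="session")
def demo_slide(tmp_path_factory):
    """Small 2x2 overlapping synthetic slide with vignetting."""
    out = tmp_path_factory.mktemp("slide")
    grid = s.TileGrid(2, 2, 600, 600, overlap=0.05, pixel_size_um=0.54)
    w, h = grid.slide_extent_um
    scene = s.demo_scene(seed=7, width_um=w, height_um=h)
    return s.render_slide(scene, grid, out, vignette=True), grid


def _match_counts(truth, records, tol_um):
    """How often each true nucleus is matched by a detection within tol."""
    from scipy.spatial import cKDTree

    tp = np.array([(t.x_um, t.y_um) for t in truth])
    dp = np.array([(r.x_um, r.y_um) for r in records])
    if len(dp) == 0:
        return np.zeros(len(tp), dtype=int), np.zeros(0, dtype=bool)
    d, i = cKDTree(tp).query(dp)
    matched = d <= tol_um
    return np.bincount(i[matched], minlength=len(tp)), matched


@pytest.fixture(scope="session")
def match_counts():
    return _match_counts
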