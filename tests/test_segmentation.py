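"""Nuclei segmentation: thresholding, splitting, refinement, morphometry."""

import numpy as np
import pytest
from skimage.draw import disk, ellipse

import slidescope as s
from slidescope.errors import ParameterError

PS = 0.54  # um/px


def single_tile_grid(size=400, pixel_size_um=PS):
    return s.TileGrid(1, 1, size, size, overlap=0.0, pixel_size_um=pixel_size_um)


# ---------------------------------------------------------------- threshold

def test_phansalkar_constant_image_closed_form():
    """T on a constant image (s=0) matches the closed form to 1e-9."""
    p = s.SegmentationParams()
    m = 0.5
    t_direct = m * (1 + p.p * np.exp(-p.q * m) + p.k * (0.0 / p.R - 1.0))
    assert t_direct == pytest.approx(0.381738, abs=1e-6)
    img = np.full((64, 64), m)
    mask = s.phansalkar_threshold(img, p)
    assert mask.all() == (m > t_direct)
    assert mask.all()


def test_phansalkar_zero_image_empty():
    assert not s.phansalkar_threshold(np.zeros((64, 64)), s.SegmentationParams()).any()


def test_phansalkar_matches_bruteforce_window_stats():
    """Bright disk on dark ground; oracle recomputes m, s per pixel."""
    rng = np.random.default_rng(5)
    img = np.full((80, 80), 0.1) + rng.normal(0, 0.005, (80, 80))
    rr, cc = disk((40, 40), 15)
    img[rr, cc] = 0.9
    img = np.clip(img, 0, 1)
    p = s.SegmentationParams(window_radius_px=7)
    mask = s.phansalkar_threshold(img, p)

    pad = np.pad(img, p.window_radius_px, mode="reflect")
    oracle = np.zeros_like(mask)
    w = 2 * p.window_radius_px + 1
    for y in range(img.shape[0]):
        for x in range(img.shape[1]):
            win = pad[y : y + w, x : x + w]
            m, sd = win.mean(), win.std()
            t = m * (1 + p.p * np.exp(-p.q * m) + p.k * (sd / p.R - 1))
            oracle[y, x] = img[y, x] > t
    assert (mask == oracle).all()
    # mask covers the disk with small boundary error
    inner = np.zeros_like(mask)
    rr, cc = disk((40, 40), 13)
    inner[rr, cc] = True
    assert mask[inner].all()
    outer = np.zeros_like(mask)
    rr, cc = disk((40, 40), 17)
    outer[rr, cc] = True
    assert not mask[~outer].any()


def test_phansalkar_window_too_large():
    with pytest.raises(ParameterError):
        s.phansalkar_threshold(np.zeros((10, 10)), s.SegmentationParams(window_radius_px=20))


# ---------------------------------------------------------------- size filter

def test_size_filter_2500_cutoff():
    # at 1 um/px: 2600 um^2 removed, 2000 um^2 retained (half-open upper bound)
    mask = np.zeros((200, 200), dtype=bool)
    mask[10:62, 10:60] = True      # 2600 px
    mask[100:140, 100:150] = True  # 2000 px
    labels = s.size_filter(mask, 10.0, 2500.0, 1.0)
    areas = np.bincount(labels.ravel())[1:]
    assert list(areas) == [2000]


def test_size_filter_empty_mask():
    labels = s.size_filter(np.zeros((32, 32), dtype=bool), 10.0, 2500.0, 1.0)
    assert labels.max() == 0


# ---------------------------------------------------------------- watershed

def test_watershed_single_disk_unsplit():
    mask = np.zeros((64, 64), dtype=bool)
    rr, cc = disk((32, 32), 12)
    mask[rr, cc] = True
    labels = s.watershed_split(mask, s.SegmentationParams())
    assert labels.max() == 1


def test_watershed_two_overlapping_disks():
    mask = np.zeros((64, 80), dtype=bool)
    for cx in (28, 40):  # centers 12 px apart, radius 10: merged blob
        rr, cc = disk((32, cx), 10)
        mask[rr, cc] = True
    from scipy import ndimage
    assert ndimage.label(mask)[1] == 1
    labels = s.watershed_split(mask, s.SegmentationParams())
    assert labels.max() == 2


def test_watershed_dumbbell_bridge():
    mask = np.zeros((64, 100), dtype=bool)
    for cx in (25, 65):
        rr, cc = disk((32, cx), 12)
        mask[rr, cc] = True
    mask[31:33, 25:65] = True  # 2-px bridge
    labels = s.watershed_split(mask, s.SegmentationParams())
    assert labels.max() == 2


def test_watershed_preserves_foreground_up_to_ridges():
    mask = np.zeros((64, 80), dtype=bool)
    for cx in (28, 40):
        rr, cc = disk((32, cx), 10)
        mask[rr, cc] = True
    labels = s.watershed_split(mask, s.SegmentationParams())
    lost = mask & (labels == 0)
    from scipy import ndimage
    # every lost pixel sits on a boundary between two output labels
    dil_a = ndimage.grey_dilation(labels, size=3)
    mn = np.where(labels == 0, labels.max() + 1, labels)
    dil_b = -ndimage.grey_dilation(-mn, size=3)
    assert ((dil_a[lost] != dil_b[lost])).all()


# ---------------------------------------------------------------- refinement

def test_channel_refine_rejects_h_poor_objects(he):
    """Eosin-rich, hematoxylin-poor mimics (corpora amylacea) are removed
    while true nuclei are kept — perfect separation by construction."""
    density = np.zeros((120, 240, 3))
    labels = np.zeros((120, 240), dtype=np.int64)
    rng = np.random.default_rng(2)
    for i in range(4):  # nuclei: H-dense
        rr, cc = disk((30 + 20 * (i % 2), 30 + 50 * i), 8)
        labels[rr, cc] = i + 1
        density[rr, cc, 0] = 1.0
    for i in range(4, 8):  # mimics: E-dense only
        rr, cc = disk((90, 30 + 50 * (i - 4)), 8)
        labels[rr, cc] = i + 1
        density[rr, cc, 1] = 1.2
    stains = s.StainImage(density=density, matrix=he)
    out = s.channel_refine(labels, stains, {0: (0.15, np.inf)})
    assert out.max() == 4
    kept = {tuple(np.argwhere(out == l).mean(0).astype(int) // 60) for l in range(1, 5)}
    assert all(r == 0 for r, _ in kept)  # only the top-row nuclei survive


def test_channel_refine_unbounded_is_identity(he):
    labels = np.zeros((32, 32), dtype=np.int64)
    labels[4:10, 4:10] = 1
    stains = s.StainImage(density=np.zeros((32, 32, 3)), matrix=he)
    out = s.channel_refine(labels, stains, {0: (-np.inf, np.inf)})
    assert (out == labels).all()


# ---------------------------------------------------------------- morphometry

def test_measure_disk_area_and_eccentricity():
    labels = np.zeros((100, 100), dtype=np.int64)
    rr, cc = disk((50, 50), 20)
    labels[rr, cc] = 1
    recs = s.measure_nuclei(labels, single_tile_grid(100), 0, 0)
    assert len(recs) == 1
    assert recs[0].area_um2 == pytest.approx(np.pi * 400 * PS**2, rel=0.02)
    assert recs[0].eccentricity < 0.05


def test_measure_ellipse_eccentricity():
    labels = np.zeros((120, 120), dtype=np.int64)
    rr, cc = ellipse(60, 60, 20, 40)  # 2:1 axes
    labels[rr, cc] = 1
    recs = s.measure_nuclei(labels, single_tile_grid(120), 0, 0)
    assert recs[0].eccentricity == pytest.approx(np.sqrt(1 - 0.25), abs=0.02)


def test_measure_respects_unique_region():
    grid = s.TileGrid(1, 2, 100, 100, overlap=0.1, pixel_size_um=1.0)
    labels = np.zeros((100, 100), dtype=np.int64)
    labels[40:50, 92:98] = 1  # centroid at x=94.5, beyond unique x-extent 90
    assert s.measure_nuclei(labels, grid, 0, 0) == []
    assert len(s.measure_nuclei(labels, grid, 0, 1)) == 1


# ---------------------------------------------------------------- end to end

def test_detection_f1_on_synthetic_tile(nuclei_tile, he, match_counts):
    rgb, truth = nuclei_tile
    grid = single_tile_grid(400)
    recs = s.segment_tile(s.deconvolve(rgb, he), grid, 0, 0)
    counts, matched = match_counts(truth, recs, 3 * PS)
    tp = int((counts >= 1).sum())
    precision = matched.sum() / max(len(recs), 1)
    recall = tp / len(truth)
    f1 = 2 * precision * recall / (precision + recall)
    assert f1 >= 0.95
    for r in recs:
        assert 10.0 <= r.area_um2 < 2500.0  # size window invariant
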