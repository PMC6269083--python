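"""Fiber orientation: gradients, circular density, summary measures, rendering."""

import numpy as np
import pytest

import slidescope as s
from slidescope.errors import InvalidTileError


def params(**kw):
    return s.FiberParams(**kw)


# ---------------------------------------------------------------- gradients

def test_gradient_of_horizontal_ramp():
    x = np.tile(np.arange(32, dtype=float), (32, 1))
    g_dir, g_mag = s.gradient_field(x)
    inner = (slice(1, -1), slice(1, -1))
    assert np.allclose(g_dir[inner], 0.0)
    assert np.allclose(g_mag[inner], 1.0)  # unit ramp -> unit magnitude


def test_gradient_of_vertical_ramp():
    y = np.tile(np.arange(32, dtype=float)[:, None], (1, 32))
    g_dir, _ = s.gradient_field(y)
    assert np.allclose(g_dir[1:-1, 1:-1], 90.0)


def test_gradient_of_sinusoid_is_horizontal():
    x = np.arange(128, dtype=float)
    img = np.tile(np.sin(2 * np.pi * x / 16), (64, 1))
    g_dir, g_mag = s.gradient_field(img)
    nz = g_mag[1:-1, 1:-1] > 1e-6
    folded = g_dir[1:-1, 1:-1][nz]
    assert np.allclose(np.minimum(folded, 180 - folded), 0.0, atol=1e-9)


# ---------------------------------------------------------------- density

def test_density_peaks_at_common_angle():
    g_dir = np.full((32, 32), 30.0)
    g_mag = np.ones_like(g_dir)
    grid, p = s.orientation_density(g_dir, g_mag, np.ones_like(g_dir, bool), params())
    assert grid[np.argmax(p)] == pytest.approx(30.0)
    assert np.trapezoid(np.append(p, p[0]), dx=1.0) == pytest.approx(1.0, abs=1e-3)


def test_density_flat_for_uniform_angles():
    rng = np.random.default_rng(12)
    g_dir = rng.uniform(0, 180, size=100_000)
    g_mag = np.ones_like(g_dir)
    _, p = s.orientation_density(g_dir, g_mag, np.ones_like(g_dir, bool), params())
    assert p.max() / p.min() < 1.1


def test_density_wraps_across_zero():
    g_dir = np.array([1.0] * 50 + [179.0] * 50)
    g_mag = np.ones_like(g_dir)
    grid, p = s.orientation_density(g_dir, g_mag, np.ones_like(g_dir, bool), params())
    assert p[np.searchsorted(grid, 0.0)] > p[np.searchsorted(grid, 90.0)]


def test_density_requires_valid_pixels():
    with pytest.raises(InvalidTileError):
        s.orientation_density(np.zeros((4, 4)), np.zeros((4, 4)),
                              np.zeros((4, 4), bool), params())


# ---------------------------------------------------------------- measures

@pytest.mark.parametrize("argmax_deg,expected_theta", [(0.0, 90.0), (120.0, 30.0)])
def test_dominant_orientation_perpendicular(argmax_deg, expected_theta):
    grid = np.arange(0.0, 180.0, 1.0)
    p = np.exp(-0.5 * ((grid - argmax_deg) / 3.0) ** 2)
    assert s.dominant_orientation(grid, p) == pytest.approx(expected_theta)


def test_relative_magnitude_bounds():
    assert s.relative_magnitude(np.full(180, 2.0)) == 0.5  # flat
    p = np.zeros(180)
    p[30] = 1.0
    assert s.relative_magnitude(p) == 1.0  # min = 0
    rng = np.random.default_rng(1)
    for _ in range(20):
        p = rng.uniform(0, 1, 180)
        assert 0.5 <= s.relative_magnitude(p) <= 1.0


def test_relative_magnitude_isotropic_noise_subtile():
    rng = np.random.default_rng(7)
    noise = rng.normal(0, 1, (64, 64))
    g_dir, g_mag = s.gradient_field(noise)
    _, p = s.orientation_density(g_dir, g_mag, np.ones_like(g_dir, bool), params())
    assert 0.5 <= s.relative_magnitude(p) <= 0.6


@pytest.mark.parametrize(
    "density,expected",
    [
        (np.stack([np.ones((4, 4)), np.zeros((4, 4)), np.zeros((4, 4))], -1), 3.0),
        (np.ones((4, 4, 3)), 1.0),
        (np.stack([np.ones((4, 4)), np.full((4, 4), 0.5), np.full((4, 4), 0.5)], -1), 1.5),
    ],
)
def test_relative_intensity_formula(density, expected, lfb):
    img = s.StainImage(density=density, matrix=lfb)
    assert s.relative_intensity(img) == pytest.approx(expected)


def test_relative_intensity_scale_invariant(lfb):
    rng = np.random.default_rng(3)
    d = rng.uniform(0, 1, (8, 8, 3))
    i1 = s.relative_intensity(s.StainImage(density=d, matrix=lfb))
    i2 = s.relative_intensity(s.StainImage(density=7.3 * d, matrix=lfb))
    assert i1 == pytest.approx(i2, rel=1e-12)


def test_relative_intensity_zero_total(lfb):
    with pytest.raises(InvalidTileError):
        s.relative_intensity(s.StainImage(density=np.zeros((4, 4, 3)), matrix=lfb))


# ---------------------------------------------------------------- pipeline

def test_blank_image_all_invalid(lfb):
    blank = np.full((128, 128, 3), 200, dtype=np.uint8)
    results = s.analyze_slide(blank, lfb, params(), 0.54)
    assert results and not any(r.valid for r in results)


def test_grating_recovery_and_validity(lfb):
    tile = s.render_fiber_tile(30.0, size_px=(256, 256), seed=4)
    results = s.analyze_slide(tile, lfb, params(), 0.54)
    valid = [r for r in results if r.valid]
    assert len(valid) >= 0.95 * len(results)
    err = np.array([min(abs(r.theta_deg - 30) % 180, 180 - abs(r.theta_deg - 30) % 180)
                    for r in valid])
    assert (err <= 2.0).mean() >= 0.95
    for r in valid:
        assert 0.5 <= r.m_rel <= 1.0
        assert 0.0 <= r.i_rel <= 3.0
        assert 0.0 <= r.theta_deg < 180.0


def test_two_region_image_classifies_by_side(lfb):
    left = s.render_fiber_tile(0.0, size_px=(128, 128), seed=5)
    right = s.render_fiber_tile(90.0, size_px=(128, 128), seed=6)
    img = np.concatenate([left, right], axis=1)
    results = s.analyze_slide(img, lfb, params(), 1.0)
    seam_col = 128 // 64 - 1  # subtile column adjacent to the seam
    for r in results:
        if not r.valid or r.col in (seam_col, seam_col + 1):
            continue
        target = 0.0 if r.col < seam_col else 90.0
        err = min(abs(r.theta_deg - target) % 180, 180 - abs(r.theta_deg - target) % 180)
        assert err <= 2.0


@pytest.mark.parametrize("delta", [15.0, 30.0, 45.0])
def test_rotation_equivariance(delta, lfb):
    base, rot = 20.0, None
    t1 = s.render_fiber_tile(base, size_px=(256, 256), seed=8)
    t2 = s.render_fiber_tile(base + delta, size_px=(256, 256), seed=8)
    def modal_theta(img):
        res = [r.theta_deg for r in s.analyze_slide(img, lfb, params(), 1.0) if r.valid]
        ang = np.radians(np.array(res) * 2)
        return np.degrees(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())) / 2 % 180
    diff = (modal_theta(t2) - modal_theta(t1)) % 180
    assert min(diff, 180 - diff) == pytest.approx(delta, abs=2.0)


def test_impurity_pixels_are_excluded(lfb):
    tile = s.render_fiber_tile(45.0, size_px=(128, 128), seed=9)
    stains = s.deconvolve(tile, lfb)
    d = stains.density.copy()
    d[:10, :10, 2] = 5.0  # heavy residual = impurity
    dirty = s.StainImage(density=d, matrix=lfb)
    res = s.analyze_image(dirty, params(), 1.0)
    assert any(r.valid for r in res)  # analysis proceeds on remaining pixels


# ---------------------------------------------------------------- rendering

def make_result(row, col, theta, m_rel=0.9, i_rel=1.5, mag=1.0, valid=True):
    return s.FiberTileResult(row=row, col=col, x_um=0, y_um=0, theta_deg=theta,
                             m_rel=m_rel, i_rel=i_rel, mean_mag=mag, valid=valid)


def test_render_hsv_black_invalid_and_circular_hue():
    results = [
        make_result(0, 0, 0.0),
        make_result(0, 1, 179.9),
        make_result(0, 2, 90.0),
        make_result(0, 3, 0.0, valid=False),
    ]
    img = s.render_hsv(results)
    assert (img[0, 3] == 0).all()  # invalid -> black
    # circular hue: 0 deg and 179.9 deg nearly identical colors
    assert np.abs(img[0, 0].astype(int) - img[0, 1].astype(int)).max() <= 3
    assert np.abs(img[0, 0].astype(int) - img[0, 2].astype(int)).max() > 50
    with pytest.raises(InvalidTileError):
        s.render_hsv([make_result(0, 0, 0.0, valid=False)])


def test_render_hsv_single_valid_subtile_full_value():
    img = s.render_hsv([make_result(0, 0, 0.0)])
    from matplotlib.colors import rgb_to_hsv

    assert rgb_to_hsv(img[0, 0] / 255.0)[2] == pytest.approx(1.0, abs=1 / 255)


@pytest.mark.parametrize(
    "theta,expected",
    [
        (0.0, (255, 0, 0)),                  # horizontal -> pure red
        (90.0, (0, 255, 0)),                 # vertical -> pure green
        (45.0, (180, 180, 0)),               # 255/sqrt(2) each
    ],
)
def test_render_rg_projection(theta, expected):
    img = s.render_rg([make_result(0, 0, theta, m_rel=1.0, i_rel=1.0)])
    assert tuple(img[0, 0]) == expected


def test_render_rg_norm_equals_weight():
    rng = np.random.default_rng(17)
    results = [
        make_result(0, i, rng.uniform(0, 180), m_rel=rng.uniform(0.5, 1.0),
                    i_rel=rng.uniform(0.1, 3.0))
        for i in range(12)
    ]
    img = s.render_rg(results)
    w = np.array([r.i_rel * r.m_rel for r in results])
    w = np.clip(w / np.percentile(w, 99), 0, 1)
    norms = np.hypot(img[0, :, 0].astype(float), img[0, :, 1].astype(float))
    assert np.abs(norms - 255.0 * w).max() <= 1.0
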