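"""Cellularity/morphometry heatmaps: binning, conservation, region summaries."""

import numpy as np
import pytest

import slidescope as s
from slidescope.errors import SlidescopeError


def rec(i, x, y, area=40.0, ecc=0.5):
    return s.NucleusRecord(id=i, x_um=x, y_um=y, area_um2=area, eccentricity=ecc,
                           source_row=0, source_col=0)


def test_four_records_one_kernel_cellularity():
    records = [rec(i, 100 + 50 * i, 200) for i in range(4)]
    hm = s.build_heatmaps(records, (1000.0, 1000.0), kernel_size_um=1000.0)
    assert hm.shape == (1, 1)
    assert hm.cellularity[0, 0] == pytest.approx(4.0)  # 4 nuclei per mm^2
    assert hm.n.sum() == 4


def test_identical_areas_zero_sd_cov():
    records = [rec(i, 10 * i + 5, 5, area=50.0) for i in range(8)]
    hm = s.build_heatmaps(records, (100.0, 100.0), kernel_size_um=100.0)
    assert hm.sd_area[0, 0] == 0.0
    assert hm.cov_area[0, 0] == 0.0
    assert hm.mean_area[0, 0] == pytest.approx(50.0)


@pytest.mark.parametrize("kernel_um", [100.0, 250.0, 333.0, 500.0])
def test_count_conservation_any_kernel_size(kernel_um):
    rng = np.random.default_rng(9)
    records = [rec(i, rng.uniform(0, 2000), rng.uniform(0, 1500)) for i in range(500)]
    hm = s.build_heatmaps(records, (2000.0, 1500.0), kernel_size_um=kernel_um)
    assert hm.n.sum() == 500


def test_halving_kernel_size_quadruples_kernel_count():
    hm1 = s.build_heatmaps([], (2000.0, 2000.0), kernel_size_um=500.0)
    hm2 = s.build_heatmaps([], (2000.0, 2000.0), kernel_size_um=250.0)
    assert hm2.n.size == 4 * hm1.n.size


def test_empty_kernels_are_undefined_not_zero():
    hm = s.build_heatmaps([rec(0, 100, 100)], (1000.0, 1000.0), kernel_size_um=500.0)
    assert np.isnan(hm.cellularity[1, 1])
    assert hm.n[1, 1] == 0


def test_edge_kernels_use_clipped_area():
    # slide 750 um wide -> second kernel column is 250 um wide
    records = [rec(0, 600.0, 100.0)]
    hm = s.build_heatmaps(records, (750.0, 500.0), kernel_size_um=500.0)
    assert hm.kernel_area_mm2[0, 1] == pytest.approx(0.25 * 0.5 / 1.0)
    assert hm.cellularity[0, 1] == pytest.approx(1 / (0.25 * 0.5))


def test_record_outside_extent_raises():
    with pytest.raises(SlidescopeError, match="ids"):
        s.build_heatmaps([rec(7, 1500.0, 100.0)], (1000.0, 1000.0), 500.0)


def test_region_summary_single_and_two_kernels():
    records = [rec(i, 100 + 20 * i, 100) for i in range(4)]  # kernel (0,0): 4/mm2
    records += [rec(10 + i, 1100 + 20 * i, 100) for i in range(8)]  # kernel (0,1)
    hm = s.build_heatmaps(records, (2000.0, 1000.0), kernel_size_um=1000.0)
    one = s.region_summary(hm, np.array([[True, False]]))
    assert one["mean"] == one["median"] == pytest.approx(4.0)
    assert one["sd"] == 0.0 and one["iqr"] == 0.0
    both = s.region_summary(hm, np.array([[True, True]]))
    assert both["mean"] == pytest.approx(6.0)
    assert both["median"] == pytest.approx(6.0)


def test_region_summary_callable_and_polygon():
    records = [rec(i, 250 + i, 250) for i in range(5)]
    hm = s.build_heatmaps(records, (1000.0, 1000.0), kernel_size_um=500.0)
    by_callable = s.region_summary(hm, lambda x, y: x < 500 and y < 500)
    from shapely.geometry import box

    by_poly = s.region_summary(hm, box(0, 0, 500, 500))
    assert by_callable == by_poly
    with pytest.raises(SlidescopeError):
        s.region_summary(hm, lambda x, y: False)


def test_render_heatmap_sidecar_and_extremes(tmp_path):
    vals = np.array([[0.0, 10.0], [np.nan, 5.0]])
    rgb = s.render_heatmap(vals, tmp_path / "m.png", upscale=1)
    back = np.loadtxt(tmp_path / "m.csv", delimiter=",")
    np.testing.assert_allclose(back, vals)
    assert (rgb[1, 0] == (40, 40, 40)).all()  # reserved undefined color
    # constant map renders uniformly
    rgb_c = s.render_heatmap(np.full((2, 2), 3.0), tmp_path / "c.png", upscale=1)
    assert (rgb_c == rgb_c[0, 0]).all()
    with pytest.raises(SlidescopeError):
        s.render_heatmap(np.full((2, 2), np.nan), tmp_path / "n.png")
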