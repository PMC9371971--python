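"""TEM pipeline: segmentation, radial measurement, pooling, mixture fits."""

import numpy as np
import pytest
from scipy import ndimage

from capkit.synthetic import TEMGeometry, TEMImage, generate_tem_image
from capkit.tem import (RingNotFoundError, ThicknessSamples,
                        aggregate_histogram, fit_thickness, radial_thickness,
                        segment_layer)


def _jaccard(a, b):
    return (a & b).sum() / (a | b).sum()


class TestSegmentLayer:
    def test_noiseless_annulus_matches_truth(self):
        img = generate_tem_image([(80.0, 0.0, 1.0)], TEMGeometry(), 0.0,
                                 seed=0)
        mask = segment_layer(img)
        assert _jaccard(mask, img.truth["ring_mask"]) >= 0.99

    def test_blank_image_raises(self):
        blank = TEMImage(pixels=np.full((64, 64), 0.5), nm_per_px=4.0)
        with pytest.raises(RingNotFoundError):
            segment_layer(blank)

    def test_robust_to_20pct_contrast_noise(self):
        # ring contrast is 0.5 intensity units; SD 0.1 = 20% of contrast
        img = generate_tem_image([(80.0, 0.0, 1.0)], TEMGeometry(), 0.1,
                                 seed=1)
        mask = segment_layer(img)
        assert _jaccard(mask, img.truth["ring_mask"]) >= 0.9


class TestRadialThickness:
    def test_circular_annulus_returns_constant_thickness(self):
        geo = TEMGeometry(wobble=0.0)
        img = generate_tem_image([(81.0, 0.0, 1.0)], geo, 0.0, seed=0)
        s = radial_thickness(img.truth["ring_mask"], geo.nm_per_px)
        assert np.all(np.abs(s.thickness_nm - 81.0) <= geo.nm_per_px + 1e-9)

    def test_ray_count_contract_on_square_ring(self):
        mask = np.zeros((101, 101), dtype=bool)
        mask[30:71, 30:71] = True
        mask[40:61, 40:61] = False
        s = radial_thickness(mask, 1.0, n_rays=4)
        assert s.angles.size == 4

    def test_normal_method_removes_secant_bias_on_elongated_cells(self):
        # inner ellipse with a constant-width band built from the distance
        # transform: normal thickness is constant by construction
        yy, xx = np.mgrid[0:301, 0:301].astype(float)
        inner = ((xx - 150) / 120) ** 2 + ((yy - 150) / 70) ** 2 <= 1.0
        d = ndimage.distance_transform_edt(~inner)
        band = 12.0
        mask = (d > 0) & (d <= band)
        ray = radial_thickness(mask, 1.0, method="ray")
        normal = radial_thickness(mask, 1.0, method="normal")
        # ray casting overestimates away from the axes; normal does not
        assert ray.thickness_nm.max() > band * 1.10
        assert abs(np.median(normal.thickness_nm) - band) / band < 0.02

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            radial_thickness(np.zeros((32, 32), dtype=bool), 1.0)


class TestAggregateHistogram:
    def _samples(self, values, cell="c0"):
        v = np.asarray(values, float)
        return ThicknessSamples(cell_id=cell,
                                angles=np.linspace(0, 6.28, v.size,
                                                   endpoint=False),
                                thickness_nm=v)

    def test_identical_samples_fill_single_bin(self):
        h = aggregate_histogram([self._samples([44.0] * 50)], bin_width=2.0)
        assert h.counts.sum() == 50
        assert (h.counts > 0).sum() == 1

    def test_counts_and_cells_recorded(self):
        cells = [self._samples(40 + 5 * np.random.default_rng(i).random(30),
                               cell=f"c{i}") for i in range(5)]
        h = aggregate_histogram(cells)
        assert h.n_cells == 5
        assert h.counts.sum() == 150

    def test_permutation_invariance(self):
        cells = [self._samples([44.0, 46.0]), self._samples([80.0, 82.0])]
        h1 = aggregate_histogram(cells)
        h2 = aggregate_histogram(cells[::-1])
        assert np.array_equal(h1.counts, h2.counts)
        assert np.array_equal(h1.bin_edges, h2.bin_edges)


class TestFitThickness:
    def test_unimodal_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.normal(81.0, 5.0, 2000)
        fit = fit_thickness(x, seed=0)
        assert fit.n_components == 1
        assert abs(fit.means[0] - 81.0) < 1.0
        assert abs(fit.sds[0] - 5.0) < 0.5

    def test_bimodal_recovery(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(44.0, 5.0, 1000),
                            rng.normal(81.0, 5.0, 1000)])
        fit = fit_thickness(x, seed=0)
        assert fit.n_components == 2
        assert abs(fit.means[0] - 44.0) < 2.0
        assert abs(fit.means[1] - 81.0) < 2.0

    def test_degenerate_sample_returns_point_mass(self):
        fit = fit_thickness(np.full(100, 60.0))
        assert fit.degenerate
        assert fit.means == (60.0,)

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError):
            fit_thickness(np.arange(10.0) + 40)


class TestEndToEnd:
    @pytest.mark.parametrize("mean_nm", [40.0, 60.0, 80.0])
    def test_mean_recovery_within_tolerance(self, mean_nm):
        geo = TEMGeometry(wobble=0.03)
        img = generate_tem_image([(mean_nm, 3.0, 1.0)], geo, 0.05, seed=7)
        mask = segment_layer(img)
        s = radial_thickness(mask, img.nm_per_px)
        fit = fit_thickness(s, seed=0)
        tol = max(0.05 * mean_nm, 2 * geo.nm_per_px)
        assert abs(fit.means[0] - mean_nm) <= tol

    def test_rotation_invariance(self):
        geo = TEMGeometry(wobble=0.03)
        img = generate_tem_image([(60.0, 4.0, 1.0)], geo, 0.05, seed=9)
        means = []
        for px in (img.pixels, np.rot90(img.pixels)):
            rot = TEMImage(pixels=px, nm_per_px=geo.nm_per_px)
            s = radial_thickness(segment_layer(rot), geo.nm_per_px)
            means.append(fit_thickness(s, seed=0).means[0])
        assert abs(means[0] - means[1]) < 1.0
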