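"""Metal segmentation, metal trace, LI-MAR and NMAR."""

import numpy as np
import pytest

from tiltmar.baselines import (MetalMask, TraceMask, build_prior, limar,
                               metal_trace, nmar, segment_metal)
from tiltmar.projection import Sinogram, forward_project
from tiltmar.recon import ReconImage, fbp

from conftest import disk_image


def img(a, px=0.3):
    return ReconImage(np.asarray(a, dtype=float), px)


@pytest.fixture(scope="module")
def rod_geom():
    """Detector fine enough to resolve sub-cm rods without heavy blooming."""
    from tiltmar.projection import FanBeamGeometry

    return FanBeamGeometry(sid_mm=400.0, sdd_mm=1100.0, n_views=240,
                           n_channels=257, fov_radius_mm=120.0)


@pytest.fixture(scope="module")
def rod_scene(rod_geom):
    """Disk of tissue with two small metal rods; sinogram + truth masks."""
    n, px = 128, 0.15
    body, x, y = disk_image(n, px, 8.0, 0.2)
    metal_true = ((x - 4) ** 2 + y ** 2 <= 0.81) | ((x + 4) ** 2 + y ** 2 <= 0.81)
    mu = body.copy()
    mu[metal_true] = 5.0
    sino = forward_project(mu, rod_geom, pixel_size=px)
    rec = fbp(sino, n=n, pixel_size=px)
    return dict(mu=mu, metal_true=metal_true, sino=sino, rec=rec, n=n, px=px)


class TestSegmentMetal:
    def test_two_components_found(self, rod_scene):
        from scipy import ndimage

        mask = segment_metal(rod_scene["rec"], thr=1.2)
        _, ncomp = ndimage.label(mask.values)
        assert ncomp == 2

    def test_area_within_blooming_tolerance(self, rod_scene):
        mask = segment_metal(rod_scene["rec"], thr=1.2)
        assert mask.values.sum() == pytest.approx(
            rod_scene["metal_true"].sum(), rel=0.30)

    def test_empty_image_warns_not_raises(self):
        with pytest.warns(UserWarning, match="threshold"):
            mask = segment_metal(img(np.full((8, 8), 0.2)), thr=1.2)
        assert not mask.values.any()


class TestMetalTrace:
    def test_empty_mask_empty_trace(self, small_geom):
        t = metal_trace(MetalMask(np.zeros((64, 64), bool), 1.2),
                        small_geom, 0.3)
        assert not t.values.any()

    def test_centered_rod_covers_central_channels_at_every_view(self, small_geom):
        mask = np.zeros((64, 64), bool)
        mask[30:34, 30:34] = True
        t = metal_trace(MetalMask(mask, 1.2), small_geom, 0.3)
        assert t.values[:, small_geom.n_channels // 2].all()

    def test_bilateral_rods_overlap_in_lateral_views(self, rod_scene, rod_geom):
        """Views along the rod axis see one merged channel interval - the
        mechanism that produces the severe 0-degree artifacts."""
        t = metal_trace(MetalMask(rod_scene["metal_true"], 1.2),
                        rod_geom, rod_scene["px"])

        def n_intervals(row):
            return int(np.count_nonzero(np.diff(np.r_[0, row.view(np.int8), 0]) == 1))

        counts = [n_intervals(t.values[iv]) for iv in range(rod_geom.n_views)]
        assert 1 in counts  # lateral views: the two traces merge
        assert 2 in counts  # AP views: traces separate


class TestLimar:
    def test_empty_trace_is_plain_fbp(self, rod_scene, small_geom):
        empty = TraceMask(np.zeros_like(rod_scene["sino"].values, dtype=bool))
        out = limar(rod_scene["sino"], empty, n=rod_scene["n"],
                    pixel_size=rod_scene["px"])
        plain = fbp(rod_scene["sino"], n=rod_scene["n"],
                    pixel_size=rod_scene["px"])
        assert np.array_equal(out.values, plain.values)

    def test_interpolation_recovers_smooth_sinogram(self, small_geom, water_disk_64):
        """Corrupting a band of a uniform disk's sinogram and inpainting it
        recovers the original values closely (smooth ground truth)."""
        sino = forward_project(water_disk_64, small_geom, pixel_size=0.3)
        trace = np.zeros_like(sino.values, dtype=bool)
        trace[:, 60:66] = True
        corrupted = sino.values.copy()
        corrupted[trace] = 99.0
        from tiltmar.baselines import _inpaint_rows

        filled = _inpaint_rows(corrupted, trace)
        good = np.abs(sino.values[trace]) > 0.2
        rel = np.abs(filled[trace] - sino.values[trace])[good] \
            / np.abs(sino.values[trace])[good]
        assert np.median(rel) < 0.02

    def test_full_row_trace_rejected(self, rod_scene):
        full = np.zeros_like(rod_scene["sino"].values, dtype=bool)
        full[3] = True
        with pytest.raises(ValueError, match="whole"):
            limar(rod_scene["sino"], TraceMask(full))

    def test_metal_reinsertion(self, rod_scene, rod_geom):
        metal = segment_metal(rod_scene["rec"], 1.2)
        trace = metal_trace(metal, rod_geom, rod_scene["px"])
        out = limar(rod_scene["sino"], trace, metal=metal,
                    uncorrected=rod_scene["rec"], n=rod_scene["n"],
                    pixel_size=rod_scene["px"])
        assert np.array_equal(out.values[metal.values],
                              rod_scene["rec"].values[metal.values])


class TestPrior:
    def test_all_air_gives_zero_prior(self):
        im = img(np.zeros((16, 16)))
        prior = build_prior(im, MetalMask(np.zeros((16, 16), bool), 1.2))
        assert not prior.values.any()

    def test_class_rules(self):
        vals = np.full((8, 8), 0.22)
        vals[0] = 0.0  # air
        vals[1] = 0.6  # bone
        metal = np.zeros((8, 8), bool)
        metal[2, 2] = True
        prior = build_prior(img(vals), MetalMask(metal, 1.2))
        tissue_val = np.median(vals[(vals >= 0.10) & (vals < 0.35) & ~metal])
        assert prior.values[0] == pytest.approx(0.0)
        assert prior.values[1] == pytest.approx(0.6)
        assert prior.values[2, 2] == pytest.approx(tissue_val)
        assert prior.values[4, 4] == pytest.approx(tissue_val)

    def test_non_monotone_thresholds_rejected(self):
        with pytest.raises(ValueError):
            build_prior(img(np.zeros((4, 4))),
                        MetalMask(np.zeros((4, 4), bool), 1.2),
                        thresholds=(0.4, 0.1))


class TestNmar:
    def test_empty_trace_is_plain_fbp(self, rod_scene):
        empty = TraceMask(np.zeros_like(rod_scene["sino"].values, dtype=bool))
        prior = build_prior(rod_scene["rec"],
                            MetalMask(np.zeros_like(rod_scene["metal_true"]), 1.2))
        out = nmar(rod_scene["sino"], empty, prior, n=rod_scene["n"],
                   pixel_size=rod_scene["px"])
        plain = fbp(rod_scene["sino"], n=rod_scene["n"],
                    pixel_size=rod_scene["px"])
        assert np.array_equal(out.values, plain.values)

    def test_inpainting_locality_outside_trace(self, rod_scene, rod_geom):
        """Outside the metal trace the inpainted sinogram equals the input:
        verified by reconstructing the difference of LI-MAR/NMAR inputs."""
        from tiltmar.baselines import _inpaint_rows

        trace = metal_trace(MetalMask(rod_scene["metal_true"], 1.2),
                            rod_geom, rod_scene["px"])
        filled = _inpaint_rows(rod_scene["sino"].values, trace.values)
        assert np.array_equal(filled[~trace.values],
                              rod_scene["sino"].values[~trace.values])

    def test_exact_prior_restores_trace(self, small_geom, water_disk_64):
        """With the true object as prior, NMAR restores trace bins closely."""
        sino = forward_project(water_disk_64, small_geom, pixel_size=0.3)
        trace = np.zeros_like(sino.values, dtype=bool)
        trace[:, 58:70] = True
        corrupted = sino.values.copy()
        corrupted[trace] += 3.0  # simulated metal corruption
        prior = img(water_disk_64)
        out_sino_img = nmar(Sinogram(corrupted, small_geom), TraceMask(trace),
                            prior, n=64, pixel_size=0.3)
        truth = fbp(sino, n=64, pixel_size=0.3)
        _, x, y = disk_image(64, 0.3, 5.0)
        inner = x * x + y * y <= 2.5 ** 2
        assert out_sino_img.values[inner].mean() == pytest.approx(
            truth.values[inner].mean(), rel=0.02)

    def test_zero_prior_rejected(self, rod_scene):
        trace = np.zeros_like(rod_scene["sino"].values, dtype=bool)
        trace[:, 60:62] = True
        zero_prior = img(np.zeros((64, 64)))
        with pytest.raises(ValueError, match="non-positive"):
            nmar(rod_scene["sino"], TraceMask(trace), zero_prior,
                 n=64, pixel_size=0.3)
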