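import numpy as np
import pytest

from _oracles import dice
from sozloc.contours import (
    detect_edges,
    extract_anatomy,
    extract_contours,
    make_reference_slice,
)
from sozloc.phantom import generate_subject


class TestReferenceSlice:
    def test_median_when_no_clusters(self):
        rng = np.random.default_rng(0)
        slices = [rng.normal(scale=0.1, size=(10, 10)) for _ in range(7)]
        ref = make_reference_slice(slices, z_threshold=2.0)
        np.testing.assert_allclose(ref, np.median(np.stack(slices), axis=0))

    def test_bright_cluster_inpainted(self):
        base = np.full((20, 20), 1.0)
        sl = base.copy()
        sl[8:11, 8:11] = 10.0
        ref = make_reference_slice([sl], z_threshold=2.0)
        np.testing.assert_allclose(ref[8:11, 8:11], 1.0, atol=1e-6)

    def test_single_slice_inpaints_own_clusters(self):
        sl = np.full((12, 12), 0.5)
        sl[2, 2] = 6.0
        ref = make_reference_slice([sl], z_threshold=2.0)
        assert abs(ref[2, 2] - 0.5) < 1e-6

    def test_empty_collection_raises(self):
        with pytest.raises(ValueError):
            make_reference_slice([])


class TestEdges:
    def test_constant_image_zero_gradient(self):
        assert detect_edges(np.full((8, 8), 3.0)).max() == 0.0

    def test_step_edge_magnitude(self):
        """A vertical step of height h gives |g| = 4h along the edge for
        the standard 3x3 Sobel kernel."""
        h = 2.5
        img = np.zeros((10, 10))
        img[5:, :] = h
        g = detect_edges(img)
        # interior pixels adjacent to the step
        assert g[4, 5] == pytest.approx(4 * h)
        assert g[5, 5] == pytest.approx(4 * h)
        assert g[2, 5] == 0.0

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(1)
        img = rng.normal(size=(9, 9))
        np.testing.assert_allclose(detect_edges(img.T), detect_edges(img).T)


def synthetic_head(n=64, r_brain=24, ring=(10, 14), spot_xy=(0, 0), spot_r=3):
    """Disk brain with a bright annulus and one dark spot in the basal
    central region; returns (image, brain, ring, spot) truth masks."""
    c = (n - 1) / 2
    X, Y = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    rho = np.sqrt((X - c) ** 2 + (Y - c) ** 2)
    brain = rho <= r_brain
    annulus = (rho >= ring[0]) & (rho <= ring[1])
    spot = (X - c - spot_xy[0]) ** 2 + (Y - c - spot_xy[1]) ** 2 <= spot_r**2
    img = np.zeros((n, n))
    img[brain] = 1.0
    img[annulus] = 1.8
    img[spot & brain] = 0.15
    return img, brain, annulus & brain, spot & brain


class TestExtract:
    def test_synthetic_head_recovered(self):
        img, brain, annulus, spot = synthetic_head()
        sc = extract_contours(detect_edges(img), img)
        assert not sc.is_empty
        assert dice(sc.periphery_mask, brain) >= 0.9
        assert len(sc.white_matter) == 1
        assert dice(sc.white_matter_mask, annulus) >= 0.9
        assert len(sc.vessels) == 1
        assert dice(sc.vessel_mask, spot) >= 0.9

    def test_blank_slice_empty(self):
        sc = extract_contours(np.zeros((16, 16)), np.zeros((16, 16)))
        assert sc.is_empty
        assert not sc.periphery_mask.any()

    def test_nested_circles_outer_is_periphery(self):
        n = 48
        c = (n - 1) / 2
        X, Y = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        rho = np.sqrt((X - c) ** 2 + (Y - c) ** 2)
        img = np.zeros((n, n))
        img[rho <= 20] = 1.0
        img[rho <= 8] = 1.8
        sc = extract_contours(detect_edges(img), img)
        assert dice(sc.periphery_mask, rho <= 20) >= 0.9

    def test_dark_spot_inside_solid_wm_discarded_as_csf(self):
        """A low-intensity region enclosed by a solid white-matter region
        is CSF, not a vessel."""
        n = 96
        c = (n - 1) / 2
        X, Y = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        rho = np.sqrt((X - c) ** 2 + (Y - c) ** 2)
        img = np.zeros((n, n))
        img[rho <= 40] = 1.0
        blob = (X - c + 15) ** 2 + (Y - c) ** 2 <= 10**2
        spot = (X - c + 15) ** 2 + (Y - c) ** 2 <= 3**2
        img[blob] = 1.8
        img[spot] = 0.15
        sc = extract_contours(detect_edges(img), img)
        assert sc.white_matter_mask.any()
        assert not (sc.vessel_mask & spot).any()

    def test_dark_spot_encircled_by_annular_wm_kept_as_vessel(self):
        """The basal vessels sit centrally, encircled by the white-matter
        band; they must survive the CSF-discard rule."""
        img, brain, annulus, spot = synthetic_head()
        sc = extract_contours(detect_edges(img), img)
        assert (sc.vessel_mask & spot).sum() > 0.5 * spot.sum()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            extract_contours(np.zeros((4, 4)), np.zeros((5, 5)))


@pytest.fixture(scope="module")
def extracted(small_subject, config):
    dec, _ = small_subject
    stack = np.stack([m.values for m in dec.ic_maps], axis=0)
    refs = [
        make_reference_slice(stack[:, :, :, s], config.z_threshold)
        for s in range(dec.dims[2])
    ]
    return extract_anatomy(refs, config)


class TestPhantomAnatomy:
    def test_containment_invariant(self, extracted):
        for sc in extracted.slices:
            inner = sc.white_matter_mask | sc.vessel_mask
            assert not (inner & ~sc.periphery_mask).any()

    def test_intensity_ordering(self, small_subject, extracted, config):
        """Mean reference intensity: WM > remaining brain > vessels."""
        dec, _ = small_subject
        stack = np.stack([m.values for m in dec.ic_maps], axis=0)
        s = dec.dims[2] // 2
        ref = make_reference_slice(stack[:, :, :, s], config.z_threshold)
        sc = extracted[s]
        assert sc.white_matter_mask.any() and sc.vessel_mask.any()
        wm = ref[sc.white_matter_mask].mean()
        gray = ref[
            sc.periphery_mask & ~sc.white_matter_mask & ~sc.vessel_mask
        ].mean()
        vessel = ref[sc.vessel_mask].mean()
        assert wm > gray > vessel

    def test_periphery_on_brain_slices(self, extracted, anatomy):
        for s in range(anatomy.n_slices):
            if anatomy.brain[:, :, s].sum() > 200:
                assert not extracted[s].is_empty
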