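import numpy as np
import pytest

from sozloc.cluster_detect import detect_clusters
from sozloc.contours import SliceContours
from sozloc.io_formats import NOISE, PipelineConfig
from sozloc.noise_stage import (
    SliceNoiseStats,
    classify_ic_noise,
    classify_slice,
    ic_slice_stats,
    slice_stats,
)
from sozloc.phantom import generate_anatomy, generate_ic


def truth_contours(anatomy, s):
    """SliceContours built directly from generator ground-truth masks."""
    shape = anatomy.brain.shape[:2]
    return SliceContours(
        shape=shape,
        periphery=np.zeros((1, 2)),
        periphery_mask=anatomy.brain[:, :, s],
        white_matter_mask=anatomy.white_matter[:, :, s],
        vessel_mask=anatomy.vessels[:, :, s],
    )


def stats(**kw):
    base = dict(
        slice_index=0, n_clusters=1, largest_cluster_size=20,
        pct_boundary_overlap=0.0, pct_wm_overlap=0.0, pct_vessel_overlap=0.0,
        outside_brain_fraction=0.0, crescent_score=0.0,
    )
    base.update(kw)
    return SliceNoiseStats(**base)


class TestSliceStats:
    def test_no_clusters_zeroed(self):
        sc = SliceContours(shape=(10, 10))
        st = slice_stats([], sc, 3)
        assert st.n_clusters == 0 and st.largest_cluster_size == 0
        assert st.pct_wm_overlap == 0.0

    def test_cluster_inside_wm_full_overlap(self, anatomy, config):
        s = anatomy.n_slices // 2
        tc = truth_contours(anatomy, s)
        wm_xy = np.argwhere(anatomy.white_matter[:, :, s])
        left = wm_xy[wm_xy[:, 0] < anatomy.brain.shape[0] // 2]
        cx, cy = left.mean(axis=0).astype(int)
        mask = np.zeros(tc.shape, dtype=bool)
        mask[cx - 2 : cx + 3, cy - 2 : cy + 3] = True
        clusters = detect_clusters(mask, config.eps, config.v_min)
        st = slice_stats(clusters, tc, s)
        assert st.pct_wm_overlap == 100.0
        assert st.outside_brain_fraction == 0.0

    def test_crescent_ratio_by_construction(self):
        """10-voxel cluster with 4 voxels in the boundary band -> 0.4."""
        shape = (30, 30)
        peri = np.zeros(shape, dtype=bool)
        peri[5:25, 5:25] = True
        sc = SliceContours(shape=shape, periphery=np.zeros((1, 2)),
                           periphery_mask=peri)
        mask = np.zeros(shape, dtype=bool)
        mask[5:7, 10:12] = True   # 4 voxels in the outer 2-voxel band
        mask[14:17, 14:16] = True  # 6 interior voxels
        # one merged cluster of 10 is needed: connect with eps large enough
        clusters = detect_clusters(mask, eps=15, v_min=1)
        assert len(clusters) == 1 and clusters[0].size == 10
        st = slice_stats(clusters, sc, 0)
        assert st.crescent_score == pytest.approx(0.4)


class TestClassifySlice:
    def test_all_zero_not_noise(self, config):
        st = stats(n_clusters=0, largest_cluster_size=0)
        assert classify_slice(st, config) == (False, "none")

    def test_wm_rule_fires(self, config):
        assert classify_slice(stats(pct_wm_overlap=90.0), config) == (
            True, "white_matter",
        )

    def test_small_cluster_rule(self, config):
        st = stats(n_clusters=40, largest_cluster_size=5)
        assert classify_slice(st, config) == (True, "small_clusters")

    def test_rule_order_outside_beats_wm(self, config):
        st = stats(outside_brain_fraction=0.9, pct_wm_overlap=90.0)
        assert classify_slice(st, config) == (True, "boundary")


class TestClassifyIC:
    def _slices(self, n_noise, n_clean, config):
        out = []
        for i in range(n_noise):
            out.append(stats(slice_index=i, pct_wm_overlap=90.0,
                             largest_cluster_size=30 - i))
        for i in range(n_clean):
            out.append(stats(slice_index=10 + i, largest_cluster_size=20 - i))
        return out

    def test_majority_noise(self, config):
        assert classify_ic_noise(self._slices(6, 4, config), config) == (
            True, "white_matter",
        )

    def test_strict_majority_required(self, config):
        assert classify_ic_noise(self._slices(5, 5, config), config) == (
            False, "none",
        )

    def test_memory_order_irrelevant(self, config):
        sl = self._slices(6, 4, config)
        assert classify_ic_noise(sl[::-1], config) == classify_ic_noise(sl, config)

    def test_empty_raises(self, config):
        with pytest.raises(ValueError):
            classify_ic_noise([], config)

    def test_no_informative_slices_not_noise(self, config):
        sl = [stats(slice_index=i, n_clusters=0, largest_cluster_size=0)
              for i in range(5)]
        assert classify_ic_noise(sl, config) == (False, "none")


class TestPhantomNoise:
    @pytest.mark.parametrize(
        "subtype,expected",
        [
            ("white_matter", "white_matter"),
            ("vessel", "vessel"),
            ("small_clusters", "small_clusters"),
            ("boundary", "boundary"),
        ],
    )
    def test_generated_noise_recovered(self, small_spec, anatomy, config,
                                       subtype, expected):
        rng = np.random.default_rng(11)
        ic, _, _ = generate_ic(small_spec, NOISE, subtype, rng=rng,
                               anatomy=anatomy)
        contours = type("A", (), {})()
        per_slice = []
        for s in range(ic.n_slices):
            from sozloc.cluster_detect import binarize_slice

            mask = binarize_slice(ic.slice(s), config.z_threshold)
            clusters = detect_clusters(mask, config.eps, config.v_min,
                                       slice_index=s)
            per_slice.append(slice_stats(clusters, truth_contours(anatomy, s), s))
        is_noise, got = classify_ic_noise(per_slice, config)
        assert is_noise and got == expected

    def test_crescent_score_high_on_top_slices(self, small_spec, anatomy, config):
        rng = np.random.default_rng(3)
        ic, _, _ = generate_ic(small_spec, NOISE, "boundary", rng=rng,
                               anatomy=anatomy)
        from sozloc.cluster_detect import binarize_slice

        scores = []
        for s in range(ic.n_slices):
            mask = binarize_slice(ic.slice(s), config.z_threshold)
            clusters = detect_clusters(mask, config.eps, config.v_min,
                                       slice_index=s)
            st = slice_stats(clusters, truth_contours(anatomy, s), s)
            if st.n_clusters:
                scores.append((st.largest_cluster_size, st.crescent_score))
        scores.sort(reverse=True)
        top = [cs for _, cs in scores[:10]]
        assert min(top) >= 0.8
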