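import numpy as np
import pytest

from sozloc.bold_features import TemporalFeatures
from sozloc.io_formats import (
    NOISE,
    RSN,
    SOZ,
    BOLDTimecourse,
    ICDecomposition,
    ICVolume,
    PipelineConfig,
)
from sozloc.phantom import PhantomSpec, generate_ic, generate_subject, rsn_templates
from sozloc.soz_classifier import (
    SOZFeatureVector,
    bullseye_score,
    classify_subject,
    ml_cluster_assign,
    rsn_template_overlap,
    rule_assign,
    wm_noise_override,
)


def fv(freq=0.03, gact=0.4, gsine=0.9, bull=0.1, gm=0.9, overlap=0.7, k=0):
    return SOZFeatureVector(
        bullseye_score=bull,
        gray_matter_fraction=gm,
        rsn_template_overlap=overlap,
        dominant_freq_hz=freq,
        gini_activelet=gact,
        gini_sine_mp=gsine,
        ic_index=k,
    )


def soz_like(k=0, rng=None):
    r = rng or np.random.default_rng(k)
    return fv(
        freq=np.clip(0.1 + r.normal(0, 0.05), 0.0, 0.25),
        gact=float(np.clip(0.85 + r.normal(0, 0.05), 0, 1)),
        bull=float(np.clip(0.9 + r.normal(0, 0.05), 0, 1)),
        overlap=float(np.clip(0.05 + r.normal(0, 0.05), 0, 1)),
        k=k,
    )


def rsn_like(k=0, rng=None):
    r = rng or np.random.default_rng(1000 + k)
    return fv(
        freq=np.clip(0.03 + r.normal(0, 0.05), 0.0, 0.25),
        gact=float(np.clip(0.4 + r.normal(0, 0.05), 0, 1)),
        bull=float(np.clip(0.1 + r.normal(0, 0.05), 0, 1)),
        overlap=float(np.clip(0.8 + r.normal(0, 0.05), 0, 1)),
        k=k,
    )


class TestBullseye:
    def _vol(self, fill):
        vals = np.zeros((40, 40, 3))
        fill(vals)
        return ICVolume(vals)

    def test_concentric_disks_score_one(self, config):
        X, Y = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        rho = np.sqrt((X - 20) ** 2 + (Y - 20) ** 2)

        def fill(v):
            v[:, :, 1][rho <= 6] = config.z_threshold + 0.1
            v[:, :, 1][rho <= 3] = 2 * config.z_threshold + 0.1

        assert bullseye_score(self._vol(fill), config) == 1.0

    def test_flat_blob_no_core_scores_zero(self, config):
        def fill(v):
            v[10:20, 10:20, 1] = config.z_threshold + 0.1

        assert bullseye_score(self._vol(fill), config) == 0.0

    def test_disjoint_blobs_at_most_half(self, config):
        def fill(v):
            v[5:15, 5:15, 1] = config.z_threshold + 0.1
            v[30:34, 30:34, 1] = 2 * config.z_threshold + 0.1

        assert bullseye_score(self._vol(fill), config) <= 0.5

    def test_empty_volume_zero(self, config):
        assert bullseye_score(ICVolume(np.zeros((10, 10, 2))), config) == 0.0


class TestTemplateOverlap:
    def test_identical_mask(self, config):
        t = np.zeros((20, 20, 4), dtype=bool)
        t[5:10, 5:10, 1] = True
        vals = np.where(t, 5.0, 0.0)
        assert rsn_template_overlap(ICVolume(vals), {"a": t},
                                    config.z_threshold) == 1.0

    def test_disjoint_zero(self, config):
        t = np.zeros((20, 20, 4), dtype=bool)
        t[0:3, 0:3, 0] = True
        vals = np.zeros((20, 20, 4))
        vals[10:13, 10:13, 2] = 5.0
        assert rsn_template_overlap(ICVolume(vals), {"a": t},
                                    config.z_threshold) == 0.0

    def test_half_overlap_dice(self, config):
        t = np.zeros((20, 20, 1), dtype=bool)
        t[0:4, 0:4, 0] = True
        vals = np.zeros((20, 20, 1))
        vals[2:6, 0:4, 0] = 5.0
        assert rsn_template_overlap(ICVolume(vals), {"a": t},
                                    config.z_threshold) == pytest.approx(0.5)

    def test_no_templates_warns_zero(self, config):
        with pytest.warns(UserWarning):
            assert rsn_template_overlap(
                ICVolume(np.ones((4, 4, 1))), {}, config.z_threshold
            ) == 0.0


class TestRuleAssign:
    def test_all_markers_soz(self, config):
        assert rule_assign(fv(freq=0.1, overlap=0.0, bull=0.9), config) == SOZ

    def test_frequency_gate(self, config):
        assert rule_assign(fv(freq=0.02, overlap=0.0, bull=0.9), config) == RSN

    def test_rsn_overlap_gate(self, config):
        assert rule_assign(fv(freq=0.1, overlap=0.8, bull=0.9), config) == RSN

    def test_sparsity_substitutes_for_bullseye(self, config):
        assert rule_assign(fv(freq=0.1, overlap=0.0, bull=0.0, gact=0.9),
                           config) == SOZ


class TestMLAssign:
    def test_two_clouds_separate(self, config):
        feats = [soz_like(k) for k in range(20)] + [rsn_like(k) for k in range(20)]
        got = ml_cluster_assign(feats, config, seed=0)
        truth = [SOZ] * 20 + [RSN] * 20
        acc = np.mean([g == t for g, t in zip(got, truth)])
        assert acc >= 0.95

    def test_identical_features_all_rsn(self, config):
        feats = [fv(k=k) for k in range(5)]
        assert ml_cluster_assign(feats, config, seed=0) == [RSN] * 5

    def test_single_ic_rule_fallback(self, config):
        got = ml_cluster_assign(
            [fv(freq=0.1, gact=0.9, bull=1.0, overlap=0.0)], config
        )
        assert got == [SOZ]

    def test_empty_raises(self, config):
        with pytest.raises(ValueError):
            ml_cluster_assign([], config)


class TestOverride:
    def _tf(self, gact, gsine=0.5):
        return TemporalFeatures(gact, gsine, 0.1, 1)

    def test_activelet_gini_above_threshold(self, config):
        assert wm_noise_override("white_matter", self._tf(0.80), config) == (
            True, "activelet_gini",
        )

    def test_below_both_thresholds(self, config):
        assert wm_noise_override("white_matter", self._tf(0.60, 0.5), config) == (
            False, "none",
        )

    def test_restricted_to_wm_subtype(self, config):
        assert wm_noise_override("boundary", self._tf(0.99), config) == (
            False, "none",
        )

    def test_sine_rule_with_attainable_threshold(self):
        cfg = PipelineConfig(gini_sine_threshold=0.7)
        assert wm_noise_override("white_matter", self._tf(0.5, 0.95), cfg) == (
            True, "sine_gini",
        )

    def test_monotone_in_gini(self, config):
        fired, _ = wm_noise_override("white_matter", self._tf(0.76), config)
        assert fired
        for g in (0.8, 0.9, 0.99):
            assert wm_noise_override("white_matter", self._tf(g), config)[0]


class TestClassifySubject:
    def test_phantom_subject_recovery(self, small_subject):
        dec, truth = small_subject
        labels = classify_subject(dec, seed=7)
        assert len(labels) == dec.n_ics
        assert sorted(l.ic_index for l in labels) == list(range(dec.n_ics))
        truth_soz = {l.ic_index for l in truth if l.category == SOZ}
        pred_soz = {l.ic_index for l in labels if l.category == SOZ}
        sens = len(truth_soz & pred_soz) / len(truth_soz)
        assert sens >= 0.8

    def test_single_noise_ic(self, small_spec, anatomy, config):
        rng = np.random.default_rng(0)
        ic, tc, _ = generate_ic(small_spec, NOISE, "boundary", rng=rng,
                                anatomy=anatomy)
        dec = ICDecomposition(ic_maps=(ic,), timecourses=(tc,),
                              tr_seconds=2.0)
        (label,) = classify_subject(dec, config=config)
        assert label.category == NOISE

    def test_seeded_determinism(self, small_subject):
        dec, _ = small_subject
        a = classify_subject(dec, seed=3)
        b = classify_subject(dec, seed=3)
        assert [(l.category, l.noise_subtype) for l in a] == [
            (l.category, l.noise_subtype) for l in b
        ]

    def test_label_exhaustiveness(self, small_subject):
        dec, _ = small_subject
        labels = classify_subject(dec, seed=7)
        cats = {l.category for l in labels}
        assert cats <= {NOISE, RSN, SOZ}
        assert len(labels) == dec.n_ics
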