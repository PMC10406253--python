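"""Second-level classification of non-noise ICs into RSN vs SOZ.

Spatial markers: a bullseye score (nested concentric activation at two
z thresholds), the fraction of suprathreshold voxels in the gray-matter
surrogate, and the best Dice overlap with the canonical resting-state
network templates.  Temporal markers: dominant frequency and the two
sparsity Gini indices.  The six features of a subject's non-noise ICs are
standardized and split into two groups by a maximum-likelihood
two-component Gaussian mixture (diagonal covariance); the component whose
mean is higher on dominant frequency, activelet Gini, and bullseye score
(majority of the three) is labeled SOZ.  A deterministic rule-based
assignment backs up degenerate cases and is available as the sole
classifier through configuration.

A white-matter-noise IC is pulled back into the SOZ pool when its BOLD
signal is sparse: activelet-domain Gini above threshold, or
sine-dictionary matching-pursuit Gini above its own (separately
configurable) threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from .bold_features import TemporalFeatures, temporal_features
from .cluster_detect import binarize_slice, detect_clusters, largest_cluster
from .contours import AnatomyContours, extract_anatomy, make_reference_slice
from .io_formats import (
    NOISE,
    RSN,
    SOZ,
    ICDecomposition,
    ICLabel,
    ICVolume,
    PipelineConfig,
)
from .noise_stage import classify_ic_noise, ic_slice_stats

__all__ = [
    "SOZFeatureVector",
    "bullseye_score",
    "rsn_template_overlap",
    "rule_assign",
    "ml_cluster_assign",
    "wm_noise_override",
    "classify_subject",
]

_FEATURE_ORDER = (
    "bullseye_score",
    "gray_matter_fraction",
    "rsn_template_overlap",
    "dominant_freq_hz",
    "gini_activelet",
    "gini_sine_mp",
)


@dataclass(frozen=True)
class SOZFeatureVector:
    """Spatial + temporal markers of one non-noise IC."""

    bullseye_score: float
    gray_matter_fraction: float
    rsn_template_overlap: float
    dominant_freq_hz: float
    gini_activelet: float
    gini_sine_mp: float
    ic_index: int = 0

    def __post_init__(self) -> None:
        for name in ("bullseye_score", "gray_matter_fraction", "rsn_template_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0, 1]: {v}")
        for name in _FEATURE_ORDER:
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite feature {name}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _FEATURE_ORDER])


def bullseye_score(ic: ICVolume, config: PipelineConfig) -> float:
    """Concentric-activation score in [0, 1].

    The map is binarized at ``z_threshold`` and ``2 * z_threshold``; the
    slice holding the largest low-threshold cluster is scored as the
    fraction of the largest high-threshold cluster enclosed by the
    low-threshold cluster, damped by half when the two cluster centroids
    are more than 3 voxels apart.  Nested concentric activation scores
    near 1, a flat blob with no high-threshold core scores 0.
    """
    best = None  # (size, slice, cluster)
    for s in range(ic.n_slices):
        mask = binarize_slice(ic.slice(s), config.z_threshold)
        clusters = detect_clusters(
            mask, config.eps, config.v_min, metric=config.metric, slice_index=s
        )
        c = largest_cluster(clusters)
        if c is not None and (best is None or c.size > best[0]):
            best = (c.size, s, c)
    if best is None:
        return 0.0
    _, s, low = best
    high_mask = binarize_slice(ic.slice(s), 2.0 * config.z_threshold)
    high = largest_cluster(
        detect_clusters(
            high_mask, config.eps, config.v_min, metric=config.metric, slice_index=s
        )
    )
    if high is None:
        return 0.0
    inside = len(high.voxels & low.voxels) / len(high.voxels)
    c_low = np.mean(sorted(low.voxels), axis=0)
    c_high = np.mean(sorted(high.voxels), axis=0)
    centroid_factor = 1.0 if np.linalg.norm(c_low - c_high) <= 3.0 else 0.5
    return float(inside * centroid_factor)


def rsn_template_overlap(
    ic: ICVolume, templates, z_threshold: float
) -> float:
    """Best Dice overlap of the suprathreshold IC mask with any template."""
    templates = dict(templates) if hasattr(templates, "items") else {
        i: t for i, t in enumerate(templates)
    }
    if not templates:
        warnings.warn("no RSN templates supplied; overlap set to 0")
        return 0.0
    mask = np.abs(ic.values) >= z_threshold
    m = mask.sum()
    best = 0.0
    for tmpl in templates.values():
        t = tmpl.astype(bool)
        denom = m + t.sum()
        if denom == 0:
            continue
        best = max(best, 2.0 * float((mask & t).sum()) / float(denom))
    return best


def rule_assign(f: SOZFeatureVector, config: PipelineConfig) -> str:
    """Deterministic marker-based RSN/SOZ call for one IC.

    SOZ requires the dominant frequency above the SOZ band edge, little
    overlap with the network templates, and either a bullseye pattern or
    a sparse (high-Gini) BOLD signal.
    """
    is_soz = (
        f.dominant_freq_hz > config.soz_freq_hz
        and f.rsn_template_overlap < config.rsn_overlap_threshold
        and (
            f.bullseye_score >= config.bullseye_threshold
            or f.gini_activelet > config.gini_activelet_threshold
        )
    )
    return SOZ if is_soz else RSN


def _standardize(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mean) / sd


def ml_cluster_assign(
    features, config: PipelineConfig, seed: int = 0
) -> list[str]:
    """Maximum-likelihood two-group split of a subject's non-noise ICs.

    Features are standardized within the subject and fit with a
    two-component diagonal-covariance Gaussian mixture (EM, k-means++
    initialization, multiple restarts); ICs are assigned by maximum
    posterior.  Degenerate inputs (a single IC, identical features) and
    EM failures fall back to the rule-based assignment; identical
    features conservatively map to RSN there unless the markers say
    otherwise.
    """
    features = list(features)
    if not features:
        raise ValueError("at least one feature vector is required")
    if len(features) < 2:
        return [rule_assign(f, config) for f in features]
    x = np.vstack([f.as_array() for f in features])
    if np.allclose(x, x[0]):
        # No structure to split on: conservatively keep everything RSN.
        return [RSN] * len(features)
    xs = _standardize(x)
    try:
        gmm = GaussianMixture(
            n_components=2,
            covariance_type="diag",
            n_init=50,
            tol=1e-6,
            max_iter=500,
            random_state=seed,
            init_params="k-means++",
        )
        assign = gmm.fit_predict(xs)
        if not gmm.converged_:
            raise ValueError("EM did not converge")
    except Exception as exc:  # noqa: BLE001 - any fit failure falls back
        warnings.warn(f"mixture fit failed ({exc}); using rule-based assignment")
        return [rule_assign(f, config) for f in features]
    # Which component is SOZ: the one with the higher mean on the majority
    # of (dominant frequency, activelet Gini, bullseye score).
    idx = [_FEATURE_ORDER.index(n) for n in
           ("dominant_freq_hz", "gini_activelet", "bullseye_score")]
    votes = sum(
        1 if gmm.means_[1][i] > gmm.means_[0][i] else 0 for i in idx
    )
    soz_comp = 1 if votes >= 2 else 0
    return [SOZ if a == soz_comp else RSN for a in assign]


def wm_noise_override(
    subtype: str, features: TemporalFeatures, config: PipelineConfig
) -> tuple[bool, str]:
    """Sparsity override for white-matter-noise ICs.

    Returns ``(reclassify, which_rule)``; only ICs with the white-matter
    noise subtype are eligible.
    """
    if subtype != "white_matter":
        return False, "none"
    if features.gini_activelet > config.gini_activelet_threshold:
        return True, "activelet_gini"
    if features.gini_sine_mp > config.gini_sine_threshold:
        return True, "sine_gini"
    return False, "none"


def _gray_matter_fraction(
    ic: ICVolume, anatomy: AnatomyContours, z_threshold: float
) -> float:
    total = 0
    in_gray = 0
    for s in range(ic.n_slices):
        mask = np.abs(ic.slice(s)) >= z_threshold
        n = int(mask.sum())
        if n == 0:
            continue
        sc = anatomy[s]
        gray = sc.periphery_mask & ~sc.white_matter_mask & ~sc.vessel_mask
        total += n
        in_gray += int((mask & gray).sum())
    return in_gray / total if total else 0.0


def subject_anatomy(
    dec: ICDecomposition, config: PipelineConfig
) -> AnatomyContours:
    """Cluster-free reference slices across all ICs, then contours."""
    stack = np.stack([m.values for m in dec.ic_maps], axis=0)
    refs = [
        make_reference_slice(stack[:, :, :, s], config.z_threshold)
        for s in range(dec.dims[2])
    ]
    return extract_anatomy(refs, config)


def classify_subject(
    dec: ICDecomposition,
    templates=None,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> list[ICLabel]:
    """Full waterfall classification of a subject's decomposition.

    Contours are extracted once from cluster-free reference slices; each
    IC then passes the noise stage, white-matter-noise ICs get the
    sparsity override, and the surviving ICs are split into RSN and SOZ.
    Exactly one label is produced per IC.
    """
    config = config if config is not None else PipelineConfig()
    config.validate(nyquist_hz=1.0 / (2.0 * dec.tr_seconds))
    if templates is None:
        from .phantom import rsn_templates

        templates = rsn_templates(dec.dims)

    anatomy = subject_anatomy(dec, config)

    labels: dict[int, ICLabel] = {}
    survivors: list[int] = []
    tf_cache: dict[int, TemporalFeatures] = {}
    noise_evidence: dict[int, dict[str, float]] = {}
    for ic, tc in zip(dec.ic_maps, dec.timecourses):
        try:
            stats = ic_slice_stats(ic, anatomy, config)
            is_noise, subtype = classify_ic_noise(stats, config)
        except Exception as exc:
            raise RuntimeError(f"noise stage failed for IC {ic.ic_index}") from exc
        informative = [s for s in stats if s.n_clusters > 0]
        evidence = {
            "max_cluster_size": float(
                max((s.largest_cluster_size for s in informative), default=0)
            ),
            "n_informative_slices": float(len(informative)),
        }
        if is_noise:
            tf = temporal_features(tc, config)
            tf_cache[ic.ic_index] = tf
            override, rule = wm_noise_override(subtype, tf, config)
            evidence.update(
                gini_activelet=tf.gini_activelet, gini_sine_mp=tf.gini_sine_mp
            )
            if override:
                # Rescued ICs keep their noise subtype as provenance and
                # compete in the RSN/SOZ stage like any survivor.
                noise_evidence[ic.ic_index] = evidence
                labels[ic.ic_index] = ICLabel(
                    ic_index=ic.ic_index,
                    category=SOZ,
                    noise_subtype=subtype,
                    override_applied=rule,
                    evidence=evidence,
                )
            else:
                labels[ic.ic_index] = ICLabel(
                    ic_index=ic.ic_index,
                    category=NOISE,
                    noise_subtype=subtype,
                    evidence=evidence,
                )
        else:
            noise_evidence[ic.ic_index] = evidence
            survivors.append(ic.ic_index)

    if survivors:
        feats = []
        for k in survivors:
            ic = dec.ic_maps[k]
            tc = dec.timecourses[k]
            tf = tf_cache.get(k) or temporal_features(tc, config)
            feats.append(
                SOZFeatureVector(
                    bullseye_score=bullseye_score(ic, config),
                    gray_matter_fraction=_gray_matter_fraction(
                        ic, anatomy, config.z_threshold
                    ),
                    rsn_template_overlap=rsn_template_overlap(
                        ic, templates, config.z_threshold
                    ),
                    dominant_freq_hz=tf.dominant_freq_hz,
                    gini_activelet=tf.gini_activelet,
                    gini_sine_mp=tf.gini_sine_mp,
                    ic_index=k,
                )
            )
        if config.classifier == "ml":
            assigned = ml_cluster_assign(feats, config, seed=seed)
        else:
            assigned = [rule_assign(f, config) for f in feats]
        for f, cat in zip(feats, assigned):
            evidence = dict(noise_evidence.get(f.ic_index, {}))
            evidence.update(
                bullseye_score=f.bullseye_score,
                gray_matter_fraction=f.gray_matter_fraction,
                rsn_template_overlap=f.rsn_template_overlap,
                dominant_freq_hz=f.dominant_freq_hz,
                gini_activelet=f.gini_activelet,
                gini_sine_mp=f.gini_sine_mp,
            )
            labels[f.ic_index] = ICLabel(
                ic_index=f.ic_index, category=cat, evidence=evidence
            )

    out = [labels[ic.ic_index] for ic in dec.ic_maps]
    assert len(out) == dec.n_ics
    return out
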