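"""Two-stage noise classification of an IC.

Stage 1 computes, for every slice, the size of the largest voxel cluster
and its percentage overlap with the brain boundary band, the white matter,
and the blood vessels.  Stage 2 sorts the slices by largest-cluster size,
keeps the ``top_k`` informative ones, classifies each against the noise
markers (activation outside the brain, high white-matter or vessel
overlap, a crescent hugging the brain boundary, or many small scattered
clusters) and calls the IC noise when a strict majority of those slices
are noise slices.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion
from skimage.morphology import disk

from .cluster_detect import VoxelCluster, binarize_slice, detect_clusters, largest_cluster
from .contours import AnatomyContours, SliceContours
from .io_formats import ICVolume, PipelineConfig

__all__ = [
    "SliceNoiseStats",
    "boundary_band",
    "slice_stats",
    "classify_slice",
    "classify_ic_noise",
    "ic_slice_stats",
]

# Fixed evaluation order of the noise rules; the subtype records the first
# rule that fires.
_RULE_ORDER = ("boundary", "white_matter", "vessel", "small_clusters")


@dataclass(frozen=True)
class SliceNoiseStats:
    """Stage-1 statistics for one slice of one IC."""

    slice_index: int
    n_clusters: int
    largest_cluster_size: int
    pct_boundary_overlap: float
    pct_wm_overlap: float
    pct_vessel_overlap: float
    outside_brain_fraction: float
    crescent_score: float

    def __post_init__(self) -> None:
        for name in ("pct_boundary_overlap", "pct_wm_overlap", "pct_vessel_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} out of [0, 100]: {v}")
        for name in ("outside_brain_fraction", "crescent_score"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0, 1]: {v}")


def boundary_band(periphery_mask: np.ndarray, width: int = 2) -> np.ndarray:
    """The band of ``width`` voxels just inside the brain periphery."""
    if not periphery_mask.any():
        return np.zeros_like(periphery_mask)
    return periphery_mask & ~binary_erosion(periphery_mask, structure=disk(width))


def _overlap_pct(cluster_mask: np.ndarray, other: np.ndarray) -> float:
    size = cluster_mask.sum()
    if size == 0:
        return 0.0
    return 100.0 * float((cluster_mask & other).sum()) / float(size)


def slice_stats(
    clusters,
    contours: SliceContours,
    slice_index: int,
    band_width: int = 2,
) -> SliceNoiseStats:
    """Overlap statistics of the detected clusters against the anatomy.

    Overlap percentages are normalized by the largest cluster's size;
    ``outside_brain_fraction`` counts all cluster voxels falling outside
    the filled periphery; the crescent score is the fraction of
    largest-cluster voxels within the boundary band.
    """
    clusters = list(clusters)
    if not clusters:
        return SliceNoiseStats(slice_index, 0, 0, 0.0, 0.0, 0.0, 0.0, 0.0)
    shape = contours.shape
    largest = largest_cluster(clusters)
    lc_mask = largest.mask(shape)

    all_mask = np.zeros(shape, dtype=bool)
    for c in clusters:
        all_mask |= c.mask(shape)

    peri = contours.periphery_mask
    band = boundary_band(peri, band_width)
    outside = 1.0 - float((all_mask & peri).sum()) / float(all_mask.sum())
    return SliceNoiseStats(
        slice_index=slice_index,
        n_clusters=len(clusters),
        largest_cluster_size=largest.size,
        pct_boundary_overlap=_overlap_pct(lc_mask, band),
        pct_wm_overlap=_overlap_pct(lc_mask, contours.white_matter_mask),
        pct_vessel_overlap=_overlap_pct(lc_mask, contours.vessel_mask),
        outside_brain_fraction=outside,
        crescent_score=float((lc_mask & band).sum()) / float(lc_mask.sum()),
    )


def classify_slice(
    stats: SliceNoiseStats, config: PipelineConfig
) -> tuple[bool, str]:
    """Apply the noise rules to one slice; the first firing rule wins."""
    if stats.n_clusters == 0:
        return False, "none"
    if stats.outside_brain_fraction > config.theta_outside:
        return True, "boundary"
    if stats.pct_wm_overlap > config.theta_wm_pct:
        return True, "white_matter"
    if stats.pct_vessel_overlap > config.theta_vessel_pct:
        return True, "vessel"
    if stats.crescent_score > config.theta_crescent:
        return True, "boundary"
    if (
        stats.n_clusters > config.theta_many_clusters
        and stats.largest_cluster_size < config.theta_small_size
    ):
        return True, "small_clusters"
    return False, "none"


def classify_ic_noise(
    per_slice, config: PipelineConfig
) -> tuple[bool, str]:
    """Majority vote over the ``top_k`` largest-cluster slices.

    Slices are sorted by largest-cluster size (descending, stable with a
    slice-index tie-break); only informative slices -- those containing at
    least one cluster -- enter the vote.  The IC is noise when strictly
    more than half of the selected slices are noise slices; the subtype is
    the modal subtype among them, ties resolved in the fixed rule order.
    """
    per_slice = list(per_slice)
    if not per_slice:
        raise ValueError("at least one slice is required")
    informative = [s for s in per_slice if s.n_clusters > 0]
    if not informative:
        return False, "none"
    informative.sort(key=lambda s: (-s.largest_cluster_size, s.slice_index))
    top = informative[: config.top_k]
    votes = [classify_slice(s, config) for s in top]
    noise_subtypes = [sub for is_noise, sub in votes if is_noise]
    if len(noise_subtypes) * 2 <= len(top):
        return False, "none"
    counts = Counter(noise_subtypes)
    best = max(counts.values())
    for subtype in _RULE_ORDER:
        if counts.get(subtype, 0) == best:
            return True, subtype
    return True, noise_subtypes[0]  # pragma: no cover - unreachable


def ic_slice_stats(
    ic: ICVolume, anatomy: AnatomyContours, config: PipelineConfig
) -> list[SliceNoiseStats]:
    """Binarize and cluster every slice of an IC and collect its stats."""
    out = []
    for s in range(ic.n_slices):
        mask = binarize_slice(ic.slice(s), config.z_threshold)
        clusters = detect_clusters(
            mask, config.eps, config.v_min, metric=config.metric, slice_index=s
        )
        out.append(
            slice_stats(clusters, anatomy[s], s, band_width=config.boundary_band_width)
        )
    return out
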