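"""The four classical IC features used by shallow-learning baselines.

For each IC: (a) the number of voxel clusters larger than a fixed pixel
size (default 135, pooled over all slices), (b) the left-right asymmetry
of the z-scored map, (c) sparsity of the BOLD signal in the activelet
basis, and (d) sparsity under sine-dictionary matching pursuit -- both
scored with the Gini index.  These are emitted as a feature table for any
external two-class classifier; no classifier is trained here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bold_features import temporal_features
from .cluster_detect import binarize_slice, detect_clusters
from .io_formats import BOLDTimecourse, ICVolume, PipelineConfig

__all__ = [
    "BaselineFeatureVector",
    "count_large_clusters",
    "asymmetry",
    "baseline_vector",
    "write_feature_table",
]


@dataclass(frozen=True)
class BaselineFeatureVector:
    n_large_clusters: int
    asymmetry: float
    gini_activelet: float
    gini_sine: float
    ic_index: int = 0

    def __post_init__(self) -> None:
        if self.n_large_clusters < 0:
            raise ValueError("cluster count cannot be negative")
        for name in ("asymmetry", "gini_activelet", "gini_sine"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite {name}")


def count_large_clusters(
    ic: ICVolume, min_px: int, config: PipelineConfig
) -> int:
    """Clusters strictly larger than ``min_px`` voxels, all slices pooled."""
    if min_px < 1:
        raise ValueError("min_px must be >= 1")
    count = 0
    for s in range(ic.n_slices):
        mask = binarize_slice(ic.slice(s), config.z_threshold)
        for c in detect_clusters(
            mask, config.eps, config.v_min, metric=config.metric, slice_index=s
        ):
            if c.size > min_px:
                count += 1
    return count


def asymmetry(ic: ICVolume, z_threshold: float = 0.0, midline: int | None = None) -> float:
    """Mean |left - mirrored right| z difference over suprathreshold voxels.

    The map is mirrored across the x midline (between columns ``nx/2 - 1``
    and ``nx/2`` for an even x dimension; pass ``midline`` to override);
    the score averages the absolute difference between each voxel and its
    contralateral partner over voxels where either side is suprathreshold.
    A perfectly mirror-symmetric map scores 0, and the score is invariant
    under mirroring of the input.
    """
    vals = ic.values
    nx = vals.shape[0]
    if midline is None and nx % 2 != 0:
        raise ValueError("odd x dimension: specify the midline explicitly")
    if midline is not None:
        # Reflect about the supplied column index boundary.
        span = min(midline, nx - midline)
        vals = vals[midline - span : midline + span]
    mirrored = vals[::-1]
    active = (np.abs(vals) >= z_threshold) | (np.abs(mirrored) >= z_threshold)
    if not active.any():
        return 0.0
    return float(np.abs(vals - mirrored)[active].mean())


def baseline_vector(
    ic: ICVolume, tc: BOLDTimecourse, config: PipelineConfig
) -> BaselineFeatureVector:
    """Assemble the four baseline features for one IC."""
    if not ic.values.any() and not tc.samples.any():
        return BaselineFeatureVector(0, 0.0, 0.0, 0.0, ic_index=ic.ic_index)
    tf = temporal_features(tc, config)
    return BaselineFeatureVector(
        n_large_clusters=count_large_clusters(
            ic, config.hunyadi_min_cluster_px, config
        ),
        asymmetry=asymmetry(ic, z_threshold=config.z_threshold),
        gini_activelet=tf.gini_activelet,
        gini_sine=tf.gini_sine_mp,
        ic_index=ic.ic_index,
    )


def write_feature_table(vectors, out_path: str | Path) -> None:
    """One CSV row per IC in a fixed column order."""
    rows = [
        {
            "ic_index": v.ic_index,
            "n_large_clusters": v.n_large_clusters,
            "asymmetry": v.asymmetry,
            "gini_activelet": v.gini_activelet,
            "gini_sine": v.gini_sine,
        }
        for v in vectors
    ]
    if not rows:
        raise ValueError("no feature vectors to write")
    pd.DataFrame(rows).to_csv(out_path, index=False)
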