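"""Reading and writing of the ICA decomposition layout.

A per-subject decomposition follows the MELODIC convention: a 4D NIfTI
volume holding one 3D spatial z-score map per independent component (IC),
plus a whitespace-delimited ``T x N`` plain-text mixing matrix whose columns
are the BOLD time courses of the ICs (``melodic_mix``).  Maps are consumed
as-is -- they are already in z-score units and are not re-standardized on
load.

Coordinate convention: voxel indices are 0-based, maps are indexed
``(x, y, slice)`` with axial slices along the third array axis.  All
slice-wise operations downstream work in voxel units on these axes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

NOISE = "noise"
RSN = "rsn"
SOZ = "soz"
CATEGORIES = (NOISE, RSN, SOZ)

NOISE_SUBTYPES = ("none", "boundary", "white_matter", "vessel", "small_clusters")
OVERRIDES = ("none", "activelet_gini", "sine_gini")


class AlignmentError(ValueError):
    """Spatial maps and time courses do not line up index-by-index."""


@dataclass(frozen=True)
class ICVolume:
    """One IC's 3D spatial z-score map.

    ``values`` is indexed ``(x, y, slice)``; ``ic_index`` is the 0-based
    position of the component within its decomposition.
    """

    values: np.ndarray
    ic_index: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"IC map must be 3D, got shape {arr.shape}")
        if arr.shape[2] < 1:
            raise ValueError("IC map needs at least one slice")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite voxels in IC {self.ic_index}")
        object.__setattr__(self, "values", arr)

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.values.shape[2]

    def slice(self, index: int) -> np.ndarray:
        """Return the 2D axial slice at ``index`` (a view, not a copy)."""
        return self.values[:, :, index]


@dataclass(frozen=True)
class BOLDTimecourse:
    """A single IC's BOLD time course sampled every ``tr_seconds``."""

    samples: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float).ravel()
        if arr.size < 1:
            raise ValueError("empty time course")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "samples", arr)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)


@dataclass(frozen=True)
class ICDecomposition:
    """An aligned collection of IC maps and time courses for one subject."""

    ic_maps: tuple[ICVolume, ...]
    timecourses: tuple[BOLDTimecourse, ...]
    subject_id: str = ""
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        maps = tuple(self.ic_maps)
        tcs = tuple(self.timecourses)
        if len(maps) != len(tcs):
            raise AlignmentError(
                f"{len(maps)} IC maps but {len(tcs)} time courses"
            )
        if len(maps) == 0:
            raise ValueError("decomposition must contain at least one IC")
        dims = maps[0].dims
        for m in maps:
            if m.dims != dims:
                raise ValueError(
                    f"IC {m.ic_index} grid {m.dims} differs from {dims}"
                )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "ic_maps", maps)
        object.__setattr__(self, "timecourses", tcs)

    @property
    def n_ics(self) -> int:
        return len(self.ic_maps)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.ic_maps[0].dims


@dataclass
class ICLabel:
    """Final category of one IC plus decision provenance.

    ``noise_subtype`` names the noise rule that claimed the IC (also kept
    when a sparsity override re-labels a white-matter-noise IC as SOZ, in
    which case ``override_applied`` records which Gini rule fired).
    ``evidence`` maps rule names to the numeric values that drove the call.
    """

    ic_index: int
    category: str
    noise_subtype: str = "none"
    override_applied: str = "none"
    evidence: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.noise_subtype not in NOISE_SUBTYPES:
            raise ValueError(f"unknown noise subtype {self.noise_subtype!r}")
        if self.override_applied not in OVERRIDES:
            raise ValueError(f"unknown override {self.override_applied!r}")
        has_subtype = self.noise_subtype != "none"
        needs_subtype = self.category == NOISE or self.override_applied != "none"
        if has_subtype != needs_subtype:
            raise ValueError(
                "noise_subtype must be set exactly when the IC is noise or "
                "an override re-labeled it"
            )
        for k, v in self.evidence.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite evidence value for {k!r}")


@dataclass
class PipelineConfig:
    """Tunable parameters of the classification pipeline.

    Density scan: ``eps`` is the neighborhood radius in voxel units and
    ``v_min`` the (strict) minimum neighbor count for a core voxel.
    Spatial maps are binarized at ``|z| >= z_threshold``.  Noise calls use
    the overlap thresholds ``theta_*``; an IC is noise when the strict
    majority of its ``top_k`` largest-cluster slices are noise slices.
    Temporal features: windows of ``window_len`` samples, ``wavelet_levels``
    undecimated wavelet levels, matching pursuit over ``mp_band_hz`` with at
    most ``mp_n_atoms`` atoms.  A white-matter-noise IC is re-labeled SOZ
    when its activelet-domain Gini exceeds ``gini_activelet_threshold`` or
    its sine-dictionary matching-pursuit Gini exceeds
    ``gini_sine_threshold``.
    """

    eps: float = 1.5
    v_min: int = 4
    metric: str = "euclidean"
    z_threshold: float = 2.3
    top_k: int = 10
    # noise-rule thresholds
    theta_outside: float = 0.5
    theta_wm_pct: float = 50.0
    theta_vessel_pct: float = 50.0
    theta_crescent: float = 0.5
    theta_many_clusters: int = 20
    theta_small_size: int = 10
    boundary_band_width: int = 2
    # contour extraction
    grad_quantile: float | None = None  # None -> Otsu threshold on gradients
    closing_radius: int = 2
    min_contour_px: int = 8
    # temporal features
    window_len: int = 256
    wavelet_levels: int = 4
    wavelet: str = "sym4"
    window_agg: str = "max"
    mp_band_hz: tuple[float, float] = (0.01, 0.1)
    mp_n_atoms: int = 10
    gini_activelet_threshold: float = 0.75
    gini_sine_threshold: float = 1.72
    soz_freq_hz: float = 0.073
    # second-level classifier
    classifier: str = "ml"  # "ml" (Gaussian-mixture) or "rule"
    rsn_overlap_threshold: float = 0.3
    bullseye_threshold: float = 0.5
    # baseline feature set
    hunyadi_min_cluster_px: int = 135

    def validate(self, nyquist_hz: float | None = None) -> None:
        low, high = self.mp_band_hz
        if not (0 < low < high):
            raise ValueError("mp_band_hz must satisfy 0 < low < high")
        if nyquist_hz is not None and high > nyquist_hz + 1e-12:
            raise ValueError(
                f"mp band edge {high} Hz exceeds Nyquist {nyquist_hz} Hz"
            )
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.window_len < 2**self.wavelet_levels:
            raise ValueError("window_len must be >= 2**wavelet_levels")
        if self.eps <= 0 or self.v_min < 1:
            raise ValueError("eps must be > 0 and v_min >= 1")
        if self.classifier not in ("ml", "rule"):
            raise ValueError("classifier must be 'ml' or 'rule'")
        if self.window_agg not in ("max", "mean"):
            raise ValueError("window_agg must be 'max' or 'mean'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mp_band_hz"] = list(self.mp_band_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        d = dict(d)
        if "mp_band_hz" in d:
            d["mp_band_hz"] = tuple(d["mp_band_hz"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_decomposition(
    ic_maps_path: str | Path,
    mix_path: str | Path,
    tr_seconds: float,
    subject_id: str | None = None,
) -> ICDecomposition:
    """Load a 4D NIfTI of IC maps plus a text mixing matrix.

    The 4th NIfTI dimension must equal the number of mixing-matrix columns;
    time course ``k`` then corresponds to map ``k``.  Non-finite voxels are
    rejected with the offending IC named.
    """
    ic_maps_path = Path(ic_maps_path)
    mix_path = Path(mix_path)
    if not ic_maps_path.exists():
        raise FileNotFoundError(f"IC map file not found: {ic_maps_path}")
    if not mix_path.exists():
        raise FileNotFoundError(f"mixing matrix not found: {mix_path}")

    img = nib.load(str(ic_maps_path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 3:
        data = data[..., np.newaxis]
    if data.ndim != 4:
        raise ValueError(f"expected a 4D NIfTI, got shape {data.shape}")

    mix = np.loadtxt(mix_path, dtype=float)
    if mix.ndim == 1:
        mix = mix[:, np.newaxis]
    n_maps = data.shape[3]
    if mix.shape[1] != n_maps:
        raise AlignmentError(
            f"{n_maps} IC maps in {ic_maps_path.name} but "
            f"{mix.shape[1]} mixing-matrix columns in {mix_path.name}"
        )

    maps = tuple(ICVolume(values=data[..., k], ic_index=k) for k in range(n_maps))
    tcs = tuple(
        BOLDTimecourse(samples=mix[:, k], tr_seconds=tr_seconds)
        for k in range(n_maps)
    )
    return ICDecomposition(
        ic_maps=maps,
        timecourses=tcs,
        subject_id=subject_id or ic_maps_path.stem,
        tr_seconds=tr_seconds,
    )


def write_decomposition(
    dec: ICDecomposition,
    ic_maps_path: str | Path,
    mix_path: str | Path,
) -> None:
    """Write a decomposition in the layout ``load_decomposition`` reads.

    Uncompressed NIfTI-1 is written so that identical inputs produce
    byte-identical files.
    """
    data = np.stack([m.values for m in dec.ic_maps], axis=3).astype(np.float32)
    img = nib.Nifti1Image(data, affine=np.eye(4))
    img.header.set_data_dtype(np.float32)
    nib.save(img, str(ic_maps_path))
    mix = np.column_stack([tc.samples for tc in dec.timecourses])
    np.savetxt(mix_path, mix, fmt="%.6f")


def _evidence_columns(labels: Sequence[ICLabel]) -> list[str]:
    keys: set[str] = set()
    for lab in labels:
        keys.update(lab.evidence)
    return sorted(keys)


def write_labels(labels: Iterable[ICLabel], out_path: str | Path) -> None:
    """Write one CSV row per IC with a deterministic column order."""
    labels = list(labels)
    if not labels:
        raise ValueError("cannot write an empty label collection")
    ev_cols = _evidence_columns(labels)
    rows = []
    for lab in labels:
        row = {
            "ic_index": lab.ic_index,
            "category": lab.category,
            "noise_subtype": lab.noise_subtype,
            "override_applied": lab.override_applied,
        }
        for k in ev_cols:
            row[k] = lab.evidence.get(k, "")
        rows.append(row)
    df = pd.DataFrame(rows, columns=["ic_index", "category", "noise_subtype",
                                     "override_applied"] + ev_cols)
    try:
        df.to_csv(out_path, index=False)
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise OSError(f"failed to write labels to {out_path}: {exc}") from exc


def read_labels(path: str | Path) -> list[ICLabel]:
    """Read back a label table written by :func:`write_labels`."""
    df = pd.read_csv(path)
    fixed = {"ic_index", "category", "noise_subtype", "override_applied"}
    labels = []
    for _, row in df.iterrows():
        evidence = {}
        for col in df.columns:
            if col in fixed:
                continue
            val = row[col]
            if pd.notna(val) and val != "":
                evidence[col] = float(val)
        labels.append(
            ICLabel(
                ic_index=int(row["ic_index"]),
                category=str(row["category"]),
                noise_subtype=str(row["noise_subtype"]),
                override_applied=str(row["override_applied"]),
                evidence=evidence,
            )
        )
    return labels
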