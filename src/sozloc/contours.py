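"""Brain periphery, white-matter, and blood-vessel contours.

The anatomy visible in the background of IC maps is recovered from a
cluster-free reference image per slice: edges are found with a Sobel
filter, the strong-gradient set is morphologically closed and each closed
edge structure is traced to a filled region.  The region that encompasses
all the others is the brain periphery; the remaining regions are sorted by
their mean reference intensity -- the brightest class is white matter, the
lowest class holds vessel/CSF candidates.  Low-intensity regions enclosed
by a white-matter region are discarded as CSF; only low-intensity regions
in the basal central area (the central third of the periphery bounding
box) are kept as blood vessels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import disk

__all__ = [
    "SliceContours",
    "AnatomyContours",
    "make_reference_slice",
    "detect_edges",
    "extract_contours",
    "extract_anatomy",
]


@dataclass
class SliceContours:
    """Contours and filled masks for one axial slice.

    ``periphery`` (and the entries of ``white_matter`` / ``vessels``) are
    closed polygons as ``(k, 2)`` float arrays of ``(x, y)`` points; the
    ``*_mask`` arrays are the corresponding filled boolean masks.  A slice
    without brain tissue carries ``periphery=None`` and all-false masks.
    """

    shape: tuple[int, int]
    periphery: np.ndarray | None = None
    periphery_mask: np.ndarray = None  # type: ignore[assignment]
    white_matter: list = field(default_factory=list)
    white_matter_mask: np.ndarray = None  # type: ignore[assignment]
    vessels: list = field(default_factory=list)
    vessel_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("periphery_mask", "white_matter_mask", "vessel_mask"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(self.shape, dtype=bool))

    @property
    def is_empty(self) -> bool:
        return self.periphery is None


@dataclass
class AnatomyContours:
    """Per-slice anatomy contours for a whole volume."""

    slices: list[SliceContours]

    def __getitem__(self, index: int) -> SliceContours:
        return self.slices[index]

    def __len__(self) -> int:
        return len(self.slices)


def make_reference_slice(
    ic_slices, z_threshold: float = 2.3
) -> np.ndarray:
    """A cluster-free background image for one slice index.

    The element-wise median across the supplied IC slices suppresses
    activation clusters, which are sparse and component-specific.  Any
    voxels still at ``|value| >= z_threshold`` afterwards (always the case
    when a single slice is supplied) are in-painted with the median
    background intensity of a surrounding annulus.
    """
    stack = np.stack([np.asarray(s, dtype=float) for s in ic_slices], axis=0)
    if stack.shape[0] < 1:
        raise ValueError("at least one slice is required")
    ref = np.median(stack, axis=0)

    residual = np.abs(ref) >= z_threshold
    if not residual.any():
        return ref
    labels, n = ndi.label(residual)
    for lab in range(1, n + 1):
        comp = labels == lab
        ring = ndi.binary_dilation(comp, iterations=3) & ~residual
        if ring.any():
            fill = float(np.median(ref[ring]))
        else:
            background = ref[~residual]
            fill = float(np.median(background)) if background.size else 0.0
        ref[comp] = fill
    return ref


def detect_edges(ref_slice: np.ndarray) -> np.ndarray:
    """Gradient magnitude from horizontal and vertical 3x3 Sobel kernels."""
    ref_slice = np.asarray(ref_slice, dtype=float)
    if not np.all(np.isfinite(ref_slice)):
        raise ValueError("reference slice contains non-finite values")
    gx = ndi.sobel(ref_slice, axis=0, mode="reflect")
    gy = ndi.sobel(ref_slice, axis=1, mode="reflect")
    return np.hypot(gx, gy)


def _edge_threshold(gradient: np.ndarray, grad_quantile: float | None) -> float:
    nonzero = gradient[gradient > 1e-12]
    if nonzero.size == 0:
        return np.inf
    if grad_quantile is not None:
        return float(np.quantile(nonzero, grad_quantile))
    if np.ptp(nonzero) < 1e-12:
        return float(nonzero.min())
    # Otsu separates the weak background-gradient mass from true edges and
    # stays stable when most of the image has near-zero gradient.
    return float(threshold_otsu(gradient))


def _region_polygon(filled: np.ndarray) -> np.ndarray | None:
    cs = measure.find_contours(filled.astype(float), 0.5)
    if not cs:
        return None
    return max(cs, key=len)


def _central_third_box(periphery_mask: np.ndarray) -> tuple[float, float, float, float]:
    xs, ys = np.nonzero(periphery_mask)
    x0, x1 = xs.min(), xs.max()
    y0, y1 = ys.min(), ys.max()
    dx = (x1 - x0) / 3.0
    dy = (y1 - y0) / 3.0
    return (x0 + dx, x1 - dx, y0 + dy, y1 - dy)


def extract_contours(
    gradient: np.ndarray,
    ref_slice: np.ndarray,
    grad_quantile: float | None = None,
    closing_radius: int = 2,
    min_contour_px: int = 8,
) -> SliceContours:
    """Classify the closed edge structures of one slice.

    Edge pixels are thresholded (Otsu by default, a fixed quantile of the
    nonzero gradients if ``grad_quantile`` is given), morphologically
    closed, and labeled.  Each labeled structure becomes a region: an
    annular structure (large interior hole) keeps its band as the region
    mask, a solid one is hole-filled; either way a one-pixel erosion strips
    the gradient halo that the Sobel operator adds on both sides of an
    intensity step.  Returns an empty-slice marker when no closed structure
    is found.
    """
    gradient = np.asarray(gradient, dtype=float)
    ref_slice = np.asarray(ref_slice, dtype=float)
    if gradient.shape != ref_slice.shape:
        raise ValueError("gradient and reference slice shapes differ")
    shape = gradient.shape
    empty = SliceContours(shape=shape)

    thr = _edge_threshold(gradient, grad_quantile)
    if not np.isfinite(thr):
        return empty
    edges = gradient >= thr
    closed = ndi.binary_closing(edges, structure=disk(closing_radius))
    labels, n = ndi.label(closed)
    if n == 0:
        return empty

    regions = []  # (mask, filled, mean_intensity, polygon)
    for lab in range(1, n + 1):
        comp = labels == lab
        if comp.sum() < min_contour_px:
            continue
        filled = ndi.binary_fill_holes(comp)
        hole = filled & ~comp
        # A closed edge band always encloses a hole; whether the structure
        # is a solid region or a true annulus is decided by intensity: if
        # the enclosed interior looks like the surrounding background
        # rather than like the band, only the band belongs to the region.
        annular = False
        if hole.sum() > 0.25 * filled.sum():
            surround = ndi.binary_dilation(filled, iterations=3) & ~filled
            if surround.any():
                hole_mean = float(ref_slice[hole].mean())
                band_mean = float(ref_slice[comp].mean())
                bg_mean = float(ref_slice[surround].mean())
                annular = abs(hole_mean - band_mean) > abs(hole_mean - bg_mean)
        mask = comp if annular else filled
        eroded = ndi.binary_erosion(mask, structure=disk(1))
        if eroded.any():
            mask = eroded
        filled_er = ndi.binary_erosion(filled, structure=disk(1))
        if filled_er.any():
            filled = filled_er
        poly = _region_polygon(filled)
        if poly is None:
            continue
        regions.append(
            {
                "mask": mask,
                "filled": filled,
                "annular": annular,
                "mean": float(ref_slice[mask].mean()),
                "poly": poly,
            }
        )
    if not regions:
        return empty

    def contains(outer: np.ndarray, inner: np.ndarray) -> bool:
        inner_n = inner.sum()
        if inner_n == 0:
            return True
        return (inner & outer).sum() >= 0.99 * inner_n

    # Periphery: the region whose filled interior contains all others.
    candidates = [
        i
        for i, r in enumerate(regions)
        if all(contains(r["filled"], q["filled"]) for j, q in enumerate(regions) if j != i)
    ]
    if candidates:
        peri_i = max(candidates, key=lambda i: regions[i]["filled"].sum())
    else:
        peri_i = max(range(len(regions)), key=lambda i: regions[i]["filled"].sum())
    peri = regions[peri_i]
    periphery_mask = peri["filled"]

    inner = [
        r
        for i, r in enumerate(regions)
        if i != peri_i and contains(periphery_mask, r["mask"])
    ]

    wm_list: list[dict] = []
    vessel_list: list[dict] = []
    if inner:
        means = np.array([r["mean"] for r in inner])
        if len(inner) == 1:
            interior = periphery_mask & ~inner[0]["mask"]
            interior_mean = (
                float(ref_slice[interior].mean()) if interior.any() else 0.0
            )
            if means[0] > interior_mean:
                wm_list = [inner[0]]
            else:
                vessel_list = [inner[0]]
        else:
            q1 = np.quantile(means, 1.0 / 3.0)
            q2 = np.quantile(means, 2.0 / 3.0)
            wm_idx = {i for i, m in enumerate(means) if m >= q2}
            wm_list = [inner[i] for i in sorted(wm_idx)]
            dark = [
                inner[i]
                for i, m in enumerate(means)
                if m <= q1 and i not in wm_idx
            ]
            # Dark regions enclosed by a solid white-matter region are CSF
            # and are discarded; a dark spot merely encircled by an annular
            # WM band sits in deep tissue and may still be a basal vessel.
            # The survivors must sit in the basal central box.
            x0, x1, y0, y1 = _central_third_box(periphery_mask)
            for r in dark:
                if any(
                    not w["annular"] and contains(w["filled"], r["mask"])
                    for w in wm_list
                ):
                    continue
                cx, cy = np.argwhere(r["mask"]).mean(axis=0)
                if x0 <= cx <= x1 and y0 <= cy <= y1:
                    vessel_list.append(r)

    wm_mask = np.zeros(shape, dtype=bool)
    for r in wm_list:
        wm_mask |= r["mask"]
    vessel_mask = np.zeros(shape, dtype=bool)
    for r in vessel_list:
        vessel_mask |= r["mask"]
    # Containment invariant: anatomy masks live inside the periphery.
    wm_mask &= periphery_mask
    vessel_mask &= periphery_mask

    return SliceContours(
        shape=shape,
        periphery=peri["poly"],
        periphery_mask=periphery_mask,
        white_matter=[r["poly"] for r in wm_list],
        white_matter_mask=wm_mask,
        vessels=[r["poly"] for r in vessel_list],
        vessel_mask=vessel_mask,
    )


def extract_anatomy(ref_slices, config=None) -> AnatomyContours:
    """Run contour extraction on every slice of a reference volume."""
    kwargs = {}
    if config is not None:
        kwargs = dict(
            grad_quantile=config.grad_quantile,
            closing_radius=config.closing_radius,
            min_contour_px=config.min_contour_px,
        )
    out = []
    for ref in ref_slices:
        grad = detect_edges(ref)
        out.append(extract_contours(grad, ref, **kwargs))
    return AnatomyContours(slices=out)
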