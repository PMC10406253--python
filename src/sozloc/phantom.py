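"""Seeded synthetic IC phantom with ground-truth labels.

The generator emulates the MELODIC output layout of a sedated pediatric
rs-fMRI acquisition: an 80 x 80 in-plane grid with 46 axial slices, ~50
components per subject, and 595 usable volumes at TR = 2 s.  Each IC map
is an anatomical background image (elliptical brain with bilateral bright
white-matter lobes and dark basal vessel spots) plus a class-specific
activation pattern and Gaussian noise:

* noise/boundary     -- a crescent hugging the brain periphery;
* noise/white_matter -- a blob inside a white-matter lobe;
* noise/vessel       -- a blob on a basal vessel;
* noise/small_clusters -- dozens of scattered 3x3 speckles;
* rsn  -- mirrored bilateral Gaussian blobs at one of eight canonical
  network sites, with a smooth 0.015-0.04 Hz time course;
* soz  -- a single concentric (bullseye) blob in gray matter away from
  the network sites, with a time course of sparse bursts riding on a
  carrier above 0.073 Hz.

Class proportions default to 60 % noise / 30 % RSN / 10 % SOZ, mirroring
the strong imbalance of clinical decompositions where fewer than one IC
in ten localizes seizure onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    NOISE,
    RSN,
    SOZ,
    BOLDTimecourse,
    ICDecomposition,
    ICLabel,
    ICVolume,
    write_decomposition,
    write_labels,
)

__all__ = [
    "PhantomSpec",
    "Anatomy",
    "generate_anatomy",
    "rsn_templates",
    "generate_ic",
    "generate_subject",
    "write_subject",
    "TEMPLATE_SITES",
]

# Bilateral network sites as (x, y) fractions of the per-slice brain
# semi-axes, mirrored across the midline.  Chosen to sit in the gray-matter
# surrogate (outside the white-matter lobes and off the basal vessels).
TEMPLATE_SITES: dict[str, tuple[float, float]] = {
    "sensorimotor": (0.45, 0.62),
    "language": (0.75, 0.25),
    "parietal": (0.45, -0.62),
    "frontal": (0.20, 0.80),
    "temporal": (0.80, -0.20),
    "visual": (0.20, -0.80),
    "default_mode": (0.10, -0.45),
    "deep_gray": (0.14, 0.0),
}

# Unilateral bullseye sites sitting in the angular gaps between network
# sites; (sign applied to x at generation time).
_SOZ_SITES: tuple[tuple[float, float], ...] = (
    (0.61, 0.44),
    (-0.61, 0.44),
    (0.61, -0.44),
    (-0.61, -0.44),
)

NOISE_SUBTYPES = ("boundary", "white_matter", "vessel", "small_clusters")

_WM_CENTER_X = 0.55  # fraction of rx
_WM_SEMI = (0.18, 0.45)  # fractions of (rx, ry)
_VESSEL_OFFSET_Y = 0.0875  # fraction of ny (fixed voxel offset on the grid)
_VESSEL_RADIUS = 3.0  # voxels
# White matter and vessels are drawn only on slices whose brain radius is
# large enough for the structures to stay well separated.
_STRUCT_MIN_RX_FRAC = 0.375  # of nx


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions of the synthetic cohort."""

    grid: tuple[int, int, int] = (80, 80, 46)
    n_ics: int = 50
    class_mix: tuple[float, float, float] = (0.6, 0.3, 0.1)
    noise_subtype_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    t_len: int = 595
    tr_seconds: float = 2.0
    seed: int = 0
    snr: float = 5.0

    def __post_init__(self) -> None:
        if self.n_ics < 1:
            raise ValueError("n_ics must be >= 1")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if abs(sum(self.noise_subtype_mix) - 1.0) > 1e-9:
            raise ValueError("noise_subtype_mix must sum to 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


@dataclass
class Anatomy:
    """Ground-truth anatomy masks (one 3D boolean array per class)."""

    brain: np.ndarray
    white_matter: np.ndarray
    vessels: np.ndarray
    gray: np.ndarray
    intensity: np.ndarray
    radii: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n_slices(self) -> int:
        return self.brain.shape[2]


def _slice_radii(spec: PhantomSpec, s: int) -> tuple[float, float]:
    nx, ny, ns = spec.grid
    zc = (ns - 1) / 2.0
    zfrac = (s - zc) / (zc * 1.02)
    scale = np.sqrt(max(0.0, 1.0 - zfrac**2))
    return 0.42 * nx * scale, 0.46 * ny * scale


def generate_anatomy(spec: PhantomSpec) -> Anatomy:
    """Elliptical brain with a smooth slice-wise radius profile.

    White matter appears as two bright bilateral lobes, blood vessels as
    dark basal spots near the slice center; gray matter is everything
    else inside the brain.  The anatomy is fully determined by the grid
    (no randomness), so identical specs give identical masks.
    """
    nx, ny, ns = spec.grid
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    brain = np.zeros(spec.grid, dtype=bool)
    wm = np.zeros(spec.grid, dtype=bool)
    vessel = np.zeros(spec.grid, dtype=bool)
    intensity = np.zeros(spec.grid, dtype=np.float32)
    radii = []
    for s in range(ns):
        rx, ry = _slice_radii(spec, s)
        radii.append((rx, ry))
        if rx < 6:
            continue
        b = ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 <= 1.0
        brain[:, :, s] = b
        intensity[:, :, s][b] = 1.0
        if rx >= _STRUCT_MIN_RX_FRAC * nx:
            for sign in (1.0, -1.0):
                wx = cx + sign * _WM_CENTER_X * rx
                w = (
                    ((X - wx) / (_WM_SEMI[0] * rx)) ** 2
                    + ((Y - cy) / (_WM_SEMI[1] * ry)) ** 2
                ) <= 1.0
                wm[:, :, s] |= w & b
            for sign in (1.0, -1.0):
                vy = cy + sign * _VESSEL_OFFSET_Y * ny
                v = (X - cx) ** 2 + (Y - vy) ** 2 <= _VESSEL_RADIUS**2
                vessel[:, :, s] |= v & b
            intensity[:, :, s][wm[:, :, s]] = 1.8
            intensity[:, :, s][vessel[:, :, s]] = 0.15
    gray = brain & ~wm & ~vessel
    return Anatomy(
        brain=brain, white_matter=wm, vessels=vessel, gray=gray,
        intensity=intensity, radii=radii,
    )


def rsn_templates(
    grid: tuple[int, int, int],
    radius: float = 4.5,
    z_half: int = 4,
) -> dict[str, np.ndarray]:
    """Schematic bilateral binary masks for the canonical networks.

    Each template is a mirrored pair of cylinders of in-plane ``radius``
    voxels centered on the network site, spanning ``2 * z_half + 1``
    middle slices.  Real-atlas masks on the same grid can be used in their
    place anywhere a template collection is accepted.
    """
    spec = PhantomSpec(grid=grid)
    nx, ny, ns = grid
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    zc = (ns - 1) // 2
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    out = {}
    for name, (fx, fy) in TEMPLATE_SITES.items():
        mask = np.zeros(grid, dtype=bool)
        for s in range(max(0, zc - z_half), min(ns, zc + z_half + 1)):
            rx, ry = _slice_radii(spec, s)
            if rx < 12:
                continue
            for sign in (1.0, -1.0):
                mx = cx + sign * fx * rx
                my = cy + fy * ry
                mask[:, :, s] |= (X - mx) ** 2 + (Y - my) ** 2 <= radius**2
        out[name] = mask
    return out


def _gaussian_blob(
    grid: tuple[int, int, int],
    center: tuple[float, float, float],
    sigma: tuple[float, float, float],
    amplitude: float,
) -> np.ndarray:
    nx, ny, ns = grid
    x = np.arange(nx)[:, None, None]
    y = np.arange(ny)[None, :, None]
    z = np.arange(ns)[None, None, :]
    d2 = (
        ((x - center[0]) / sigma[0]) ** 2
        + ((y - center[1]) / sigma[1]) ** 2
        + ((z - center[2]) / sigma[2]) ** 2
    )
    return (amplitude * np.exp(-0.5 * d2)).astype(np.float32)


def _mid_slices(spec: PhantomSpec, min_rx: float = 12.0) -> np.ndarray:
    ns = spec.grid[2]
    return np.array(
        [s for s in range(ns) if _slice_radii(spec, s)[0] >= min_rx]
    )


def _noise_activation(
    spec: PhantomSpec,
    subtype: str,
    rng: np.random.Generator,
    anatomy: Anatomy | None = None,
) -> np.ndarray:
    nx, ny, ns = spec.grid
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    act = np.zeros(spec.grid, dtype=np.float32)
    mid = _mid_slices(spec)
    zc = (ns - 1) / 2.0

    if subtype == "boundary":
        theta0 = rng.uniform(0, 2 * np.pi)
        X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        lo = int(zc - 7), int(zc + 7)
        for s in range(lo[0], lo[1] + 1):
            rx, ry = _slice_radii(spec, s)
            if rx < 12:
                continue
            rho = np.sqrt(((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2)
            theta = np.arctan2(Y - cy, X - cx)
            arc = np.mod(theta - theta0, 2 * np.pi) <= np.pi
            act[:, :, s][(rho >= 0.94) & (rho <= 1.0) & arc] = 5.0
    elif subtype == "white_matter":
        sign = rng.choice([-1.0, 1.0])
        s0 = zc + rng.integers(-2, 3)
        rx, ry = _slice_radii(spec, int(round(s0)))
        center = (cx + sign * _WM_CENTER_X * rx, cy, float(s0))
        act = _gaussian_blob(spec.grid, center, (2.4, 2.4, 2.5), 6.0)
    elif subtype == "vessel":
        sign = rng.choice([-1.0, 1.0])
        s0 = zc + rng.integers(-2, 3)
        center = (cx, cy + sign * _VESSEL_OFFSET_Y * ny, float(s0))
        act = _gaussian_blob(spec.grid, center, (1.8, 1.8, 2.0), 6.0)
    elif subtype == "small_clusters":
        anatomy = anatomy if anatomy is not None else generate_anatomy(spec)
        slices = mid[np.abs(mid - zc) <= 6]
        # 3x3 speckles on a coarse lattice: small (9 voxels) and mutually
        # separated so the density scan keeps them distinct; placed in the
        # gray-matter surrogate so no single speckle overlaps white matter
        # or a vessel.
        from scipy.ndimage import binary_dilation, binary_erosion

        for s in slices:
            rx, ry = _slice_radii(spec, s)
            allowed = anatomy.gray[:, :, s] & ~binary_dilation(
                anatomy.white_matter[:, :, s] | anatomy.vessels[:, :, s],
                iterations=3,
            )
            allowed = binary_erosion(allowed, iterations=2)
            lattice = [
                (i, j)
                for i in range(3, nx - 3, 6)
                for j in range(3, ny - 3, 6)
                if allowed[i, j]
                and ((i - cx) / rx) ** 2 + ((j - cy) / ry) ** 2 < 0.85**2
            ]
            picks = rng.choice(len(lattice), size=min(26, len(lattice)), replace=False)
            for p in picks:
                i, j = lattice[p]
                act[i - 1 : i + 2, j - 1 : j + 2, s] = 5.0
    else:
        raise ValueError(f"unknown noise subtype {subtype!r}")
    return act


def _rsn_activation(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[np.ndarray, str]:
    nx, ny, ns = spec.grid
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    zc = (ns - 1) / 2.0
    name = list(TEMPLATE_SITES)[rng.integers(len(TEMPLATE_SITES))]
    fx, fy = TEMPLATE_SITES[name]
    s0 = float(zc + rng.integers(-1, 2))
    rx, ry = _slice_radii(spec, int(round(s0)))
    jx, jy = rng.uniform(-1, 1, size=2)
    act = np.zeros(spec.grid, dtype=np.float32)
    for sign in (1.0, -1.0):
        center = (cx + sign * (fx * rx + jx), cy + fy * ry + jy, s0)
        act += _gaussian_blob(spec.grid, center, (3.2, 3.2, 2.5), 6.5)
    return act, name


def _soz_activation(
    spec: PhantomSpec, rng: np.random.Generator
) -> np.ndarray:
    nx, ny, ns = spec.grid
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    zc = (ns - 1) / 2.0
    fx, fy = _SOZ_SITES[rng.integers(len(_SOZ_SITES))]
    s0 = float(zc + rng.integers(-4, 5))
    rx, ry = _slice_radii(spec, int(round(s0)))
    center = (cx + fx * rx, cy + fy * ry, s0)
    return _gaussian_blob(spec.grid, center, (3.0, 3.0, 2.2), 7.5)


def _noise_timecourse(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(size=spec.t_len)


def _rsn_timecourse(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(spec.t_len) * spec.tr_seconds
    f = rng.uniform(0.015, 0.04)
    phase = rng.uniform(0, 2 * np.pi)
    return np.sin(2 * np.pi * f * t + phase) + 0.1 * rng.normal(size=spec.t_len)


def _soz_timecourse(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(spec.t_len) * spec.tr_seconds
    f = rng.uniform(0.085, 0.098)
    phase = rng.uniform(0, 2 * np.pi)
    envelope = np.zeros(spec.t_len)
    n_bursts = int(rng.integers(2, 5))
    # Bursts stay within the first two 256-sample windows so the windowed
    # sparsity analysis always sees them.
    hi = min(spec.t_len - 30, 480)
    centers = rng.choice(np.arange(30, hi), size=n_bursts, replace=False)
    for c in centers:
        envelope += np.exp(-0.5 * ((np.arange(spec.t_len) - c) / 3.0) ** 2)
    sig = envelope * np.sin(2 * np.pi * f * t + phase)
    return sig + 0.008 * rng.normal(size=spec.t_len)


def generate_ic(
    spec: PhantomSpec,
    cls: str,
    subtype: str = "none",
    rng: np.random.Generator | None = None,
    anatomy: Anatomy | None = None,
    ic_index: int = 0,
) -> tuple[ICVolume, BOLDTimecourse, ICLabel]:
    """One IC map + time course + ground-truth label of the given class."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    anatomy = anatomy if anatomy is not None else generate_anatomy(spec)
    evidence: dict[str, float] = {}
    if cls == NOISE:
        act = _noise_activation(spec, subtype, rng, anatomy=anatomy)
        tc = _noise_timecourse(spec, rng)
    elif cls == RSN:
        act, _ = _rsn_activation(spec, rng)
        tc = _rsn_timecourse(spec, rng)
        subtype = "none"
    elif cls == SOZ:
        act = _soz_activation(spec, rng)
        tc = _soz_timecourse(spec, rng)
        subtype = "none"
    else:
        raise ValueError(f"unknown IC class {cls!r}")

    sigma = 1.0 / spec.snr
    values = (
        anatomy.intensity
        + act
        + rng.normal(scale=sigma, size=spec.grid).astype(np.float32)
    ).astype(np.float32)
    label = ICLabel(
        ic_index=ic_index, category=cls, noise_subtype=subtype, evidence=evidence
    )
    vol = ICVolume(values=values, ic_index=ic_index)
    return vol, BOLDTimecourse(samples=tc, tr_seconds=spec.tr_seconds), label


def _largest_remainder(total: int, proportions) -> list[int]:
    raw = np.asarray(proportions, dtype=float) * total
    base = np.floor(raw).astype(int)
    remainder = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in range(remainder):
        base[order[i]] += 1
    return base.tolist()


def generate_subject(
    spec: PhantomSpec,
) -> tuple[ICDecomposition, list[ICLabel]]:
    """A full phantom subject: ``n_ics`` ICs drawn per the class mix.

    Class and noise-subtype counts follow the mix proportions with
    deterministic (largest-remainder) rounding; the IC order is shuffled
    with the spec's seed.  Returns the decomposition and the aligned
    ground-truth labels.
    """
    rng = np.random.default_rng(spec.seed)
    anatomy = generate_anatomy(spec)
    n_noise, n_rsn, n_soz = _largest_remainder(spec.n_ics, spec.class_mix)
    subtype_counts = _largest_remainder(n_noise, spec.noise_subtype_mix)

    plan: list[tuple[str, str]] = []
    for subtype, count in zip(NOISE_SUBTYPES, subtype_counts):
        plan.extend([(NOISE, subtype)] * count)
    plan.extend([(RSN, "none")] * n_rsn)
    plan.extend([(SOZ, "none")] * n_soz)
    order = rng.permutation(len(plan))

    maps, tcs, labels = [], [], []
    for new_index, plan_index in enumerate(order):
        cls, subtype = plan[plan_index]
        vol, tc, label = generate_ic(
            spec, cls, subtype, rng=rng, anatomy=anatomy, ic_index=new_index
        )
        maps.append(vol)
        tcs.append(tc)
        labels.append(label)
    dec = ICDecomposition(
        ic_maps=tuple(maps),
        timecourses=tuple(tcs),
        subject_id=f"phantom-{spec.seed}",
        tr_seconds=spec.tr_seconds,
    )
    return dec, labels


def write_subject(
    dec: ICDecomposition, labels, out_dir: str | Path
) -> dict[str, Path]:
    """Write the standard layout: IC maps, mixing matrix, truth labels."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ic_maps": out_dir / "melodic_IC.nii",
        "mix": out_dir / "melodic_mix",
        "truth": out_dir / "truth_labels.csv",
    }
    write_decomposition(dec, paths["ic_maps"], paths["mix"])
    write_labels(labels, paths["truth"])
    return paths
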