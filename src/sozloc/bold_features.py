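"""Temporal features of IC BOLD time courses.

The signal is split into non-overlapping windows and each window is pushed
through two sparsity analyses: an undecimated (à-trous) wavelet transform
whose detail-coefficient sparsity is scored with the Gini index, and a
greedy matching pursuit over a dictionary of sine/cosine atoms restricted
to the low-frequency BOLD band, whose coefficient-vector sparsity is again
scored with the Gini index.  Event-like (burst) activity, the temporal
signature of seizure onset, is sparse in both representations, while
smooth resting-state oscillations are not.  The dominant frequency of the
full time course is read from its periodogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import periodogram

from .io_formats import BOLDTimecourse, PipelineConfig

__all__ = [
    "TemporalFeatures",
    "window_signal",
    "activelet_decompose",
    "activelet_reconstruct",
    "gini_index",
    "sine_dictionary",
    "matching_pursuit",
    "sine_mp_gini",
    "dominant_frequency",
    "temporal_features",
]


@dataclass(frozen=True)
class TemporalFeatures:
    """Aggregated temporal markers of one IC."""

    gini_activelet: float
    gini_sine_mp: float
    dominant_freq_hz: float
    windows_used: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.gini_activelet <= 1.0:
            raise ValueError("gini_activelet out of [0, 1]")
        if self.dominant_freq_hz < 0:
            raise ValueError("dominant frequency must be nonnegative")
        if self.windows_used < 1:
            raise ValueError("windows_used must be >= 1")


def window_signal(tc: BOLDTimecourse, window_len: int) -> list[np.ndarray]:
    """Non-overlapping consecutive windows of ``window_len`` samples.

    A signal shorter than one window is zero-padded into a single window;
    otherwise the trailing remainder is discarded.
    """
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    x = tc.samples
    if x.size == 0:
        raise ValueError("empty signal")
    if x.size < window_len:
        padded = np.zeros(window_len)
        padded[: x.size] = x
        return [padded]
    n_win = x.size // window_len
    return [x[i * window_len : (i + 1) * window_len].copy() for i in range(n_win)]


def activelet_decompose(
    window: np.ndarray, levels: int = 4, wavelet: str = "sym4"
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Undecimated wavelet decomposition of one window.

    Returns ``(approximation, details)`` where ``details`` holds the
    ``levels`` detail bands ordered coarse to fine; every band has the
    window's length.  The transform is linear and admits exact
    reconstruction via :func:`activelet_reconstruct`.  The window length
    must be a multiple of ``2**levels`` (and in particular at least that
    long), which the windowing above guarantees for its defaults.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 1:
        raise ValueError("window must be 1D")
    step = 2**levels
    if window.size < step:
        raise ValueError(
            f"window of {window.size} samples is too short for {levels} levels"
        )
    if window.size % step:
        raise ValueError(
            f"window length {window.size} is not a multiple of 2**{levels}"
        )
    coeffs = pywt.swt(window, wavelet, level=levels, norm=True, trim_approx=True)
    approx = coeffs[0]
    details = list(coeffs[1:])
    return approx, details


def activelet_reconstruct(
    approx: np.ndarray, details: list[np.ndarray], wavelet: str = "sym4"
) -> np.ndarray:
    """Invert :func:`activelet_decompose`."""
    return pywt.iswt([np.asarray(approx)] + [np.asarray(d) for d in details],
                     wavelet, norm=True)


def gini_index(coeffs: np.ndarray) -> float:
    """Gini sparsity of a coefficient vector.

    With magnitudes sorted ascending ``c(1) <= ... <= c(N)`` and L1 norm
    ``S``::

        G = 1 - 2 * sum_k (c(k) / S) * ((N - k + 0.5) / N)

    ``G`` is scale-invariant, 0 for constant magnitudes and ``(N-1)/N``
    for a one-hot vector.  An all-zero input returns 0 by convention.
    """
    c = np.abs(np.asarray(coeffs, dtype=float).ravel())
    n = c.size
    if n == 0:
        raise ValueError("empty coefficient vector")
    s = c.sum()
    if s == 0:
        return 0.0
    c = np.sort(c)
    k = np.arange(1, n + 1)
    g = 1.0 - 2.0 * np.sum((c / s) * ((n - k + 0.5) / n))
    # guard against -1e-16 style rounding on constant vectors
    return float(min(max(g, 0.0), 1.0))


def sine_dictionary(
    window_len: int, band_hz: tuple[float, float], tr_seconds: float
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-norm sine and cosine atoms on the window's frequency grid.

    Frequencies are spaced ``1 / (window_len * TR)`` apart and restricted
    to ``band_hz``.  Returns ``(atoms, freqs)`` with ``atoms`` of shape
    ``(n_atoms, window_len)`` and ``freqs`` the frequency of each atom.
    """
    low, high = band_hz
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not (0 < low < high <= nyquist + 1e-12):
        raise ValueError(f"band {band_hz} outside (0, Nyquist={nyquist}]")
    df = 1.0 / (window_len * tr_seconds)
    k_lo = int(np.ceil(low / df - 1e-9))
    k_hi = int(np.floor(high / df + 1e-9))
    freqs = df * np.arange(max(k_lo, 1), k_hi + 1)
    if freqs.size == 0:
        raise ValueError(
            f"band {band_hz} Hz is below the frequency resolution {df} Hz"
        )
    t = np.arange(window_len) * tr_seconds
    atoms = []
    out_freqs = []
    for f in freqs:
        for phase in (np.sin, np.cos):
            atom = phase(2.0 * np.pi * f * t)
            norm = np.linalg.norm(atom)
            if norm > 1e-12:
                atoms.append(atom / norm)
                out_freqs.append(f)
    return np.array(atoms), np.array(out_freqs)


def matching_pursuit(
    window: np.ndarray,
    atoms: np.ndarray,
    n_atoms: int = 10,
    residual_frac: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy matching pursuit of ``window`` over ``atoms``.

    At each step the atom with the largest absolute inner product with the
    residual is selected and its projection removed.  Stops after
    ``n_atoms`` selections or when the residual energy falls below
    ``residual_frac`` of the initial energy.  Returns ``(coefficients,
    residual)`` with one (possibly zero) coefficient per atom; residual
    energy is non-increasing by construction.
    """
    r = np.asarray(window, dtype=float).copy()
    coeffs = np.zeros(atoms.shape[0])
    e0 = float(r @ r)
    if e0 == 0:
        return coeffs, r
    prev = e0
    for _ in range(n_atoms):
        ip = atoms @ r
        k = int(np.argmax(np.abs(ip)))
        if abs(ip[k]) < 1e-14:
            break
        coeffs[k] += ip[k]
        r = r - ip[k] * atoms[k]
        e = float(r @ r)
        if e > prev + 1e-9 * e0:
            raise AssertionError("matching-pursuit residual energy increased")
        prev = e
        if e < residual_frac * e0:
            break
    return coeffs, r


def sine_mp_gini(
    window: np.ndarray,
    band_hz: tuple[float, float],
    tr_seconds: float,
    n_atoms: int = 10,
) -> float:
    """Gini index of the matching-pursuit coefficients over the full
    sine dictionary (unselected atoms contribute zeros)."""
    window = np.asarray(window, dtype=float)
    atoms, _ = sine_dictionary(window.size, band_hz, tr_seconds)
    if not window.any():
        return 0.0
    coeffs, _ = matching_pursuit(window, atoms, n_atoms=n_atoms)
    return gini_index(coeffs)


def dominant_frequency(
    tc: BOLDTimecourse, band_hz: tuple[float, float]
) -> float:
    """Frequency of maximal periodogram power within ``[low, Nyquist]``.

    The mean is removed first.  A signal with no power in the band (e.g. a
    constant) returns the band's low edge.
    """
    if tc.n_samples < 8:
        raise ValueError("need at least 8 samples")
    low, _ = band_hz
    x = tc.samples - tc.samples.mean()
    freqs, power = periodogram(x, fs=1.0 / tc.tr_seconds)
    sel = freqs >= low
    if not sel.any() or power[sel].max() <= 0:
        return float(low)
    freqs, power = freqs[sel], power[sel]
    return float(freqs[int(np.argmax(power))])


def temporal_features(
    tc: BOLDTimecourse, config: PipelineConfig
) -> TemporalFeatures:
    """Windowed sparsity features plus the full-signal dominant frequency.

    The activelet Gini of each window is computed on the concatenated
    detail bands (the approximation carries baseline, not transients) and
    windows are aggregated with ``config.window_agg`` (max by default: a
    single seizure-bearing window should dominate the score).
    """
    config.validate(nyquist_hz=tc.nyquist_hz)
    windows = window_signal(tc, config.window_len)
    if not tc.samples.any():
        return TemporalFeatures(0.0, 0.0, 0.0, windows_used=len(windows))
    g_act, g_sine = [], []
    for w in windows:
        if not w.any():
            g_act.append(0.0)
            g_sine.append(0.0)
            continue
        _, details = activelet_decompose(
            w, levels=config.wavelet_levels, wavelet=config.wavelet
        )
        g_act.append(gini_index(np.concatenate(details)))
        g_sine.append(
            sine_mp_gini(w, config.mp_band_hz, tc.tr_seconds, config.mp_n_atoms)
        )
    agg = max if config.window_agg == "max" else (lambda v: float(np.mean(v)))
    return TemporalFeatures(
        gini_activelet=float(agg(g_act)),
        gini_sine_mp=float(agg(g_sine)),
        dominant_freq_hz=dominant_frequency(tc, config.mp_band_hz),
        windows_used=len(windows),
    )
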