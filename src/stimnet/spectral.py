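"""Multitaper spectral estimation (DPSS tapers).

All spectral quantities in the package flow through this module: averaged
cross-spectral matrices for coherence networks and band power for the
pre/post stimulation contrast. Tapers are discrete prolate spheroidal
sequences with a fixed time-bandwidth product; tapers whose spectral
concentration falls below a cutoff are discarded.

Conventions: one-sided power spectral density in units of (input unit)^2/Hz,
unit-energy tapers, uniform (non-adaptive) weighting across tapers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import dpss

__all__ = [
    "MultitaperSpec",
    "dpss_tapers",
    "multitaper_cross_spectra",
    "trial_band_power",
    "band_power_matrix",
]


@dataclass(frozen=True)
class MultitaperSpec:
    """Multitaper parameters.

    time_bandwidth : NW product (dimensionless); sets the half-bandwidth
        NW/T Hz of spectral smoothing for a window of length T seconds.
    max_tapers : upper bound on the taper count (at most 2*NW - 1 are
        well concentrated).
    min_concentration : tapers with spectral concentration below this are
        dropped.
    """

    time_bandwidth: float = 4.0
    max_tapers: int = 8
    min_concentration: float = 0.9

    def __post_init__(self) -> None:
        if self.time_bandwidth <= 0:
            raise ValueError("time_bandwidth must be positive")
        if self.max_tapers < 1:
            raise ValueError("max_tapers must be >= 1")
        if not 0 < self.min_concentration < 1:
            raise ValueError("min_concentration must lie in (0, 1)")


def dpss_tapers(n_samples: int, spec: MultitaperSpec) -> np.ndarray:
    """DPSS tapers (n_tapers, n_samples), concentration-filtered, unit energy."""
    if n_samples < 2 * spec.time_bandwidth:
        raise ValueError(
            f"window of {n_samples} samples too short for NW={spec.time_bandwidth}"
        )
    tapers, ratios = dpss(
        n_samples, spec.time_bandwidth, Kmax=spec.max_tapers, return_ratios=True
    )
    keep = ratios >= spec.min_concentration
    if not keep.any():
        raise ValueError("no taper meets the concentration cutoff")
    return tapers[keep]


def _freqs(n_samples: int, fs: float) -> np.ndarray:
    return np.fft.rfftfreq(n_samples, d=1.0 / fs)


def multitaper_cross_spectra(
    windows: np.ndarray,
    spec: MultitaperSpec,
    fs: float,
    fmin: float = 0.0,
    fmax: float | None = None,
    chunk: int = 16,
) -> tuple[np.ndarray, np.ndarray]:
    """Averaged cross-spectral density matrices.

    Parameters
    ----------
    windows : ndarray, shape (n_windows, n_channels, n_samples)
        Equal-length data segments.
    fmin, fmax : Hz
        Frequency range to retain (bin centers, endpoints inclusive).

    Returns
    -------
    freqs : ndarray, shape (n_freqs,)
    S : ndarray, shape (n_freqs, n_channels, n_channels), complex
        Cross-spectral density averaged over tapers and windows; Hermitian
        at every frequency. ``S[f, x, x]`` is the (real) PSD of channel x.
    """
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 3:
        raise ValueError("windows must be (n_windows, n_channels, n_samples)")
    n_win, n_ch, n_samp = windows.shape
    if n_win < 1:
        raise ValueError("need at least one window")
    tapers = dpss_tapers(n_samp, spec)
    n_tap = tapers.shape[0]
    freqs = _freqs(n_samp, fs)
    if fmax is None:
        fmax = fs / 2
    sel = (freqs >= fmin) & (freqs <= fmax)
    if not sel.any():
        raise ValueError(f"no frequency bins inside [{fmin}, {fmax}] Hz")
    freqs = freqs[sel]
    n_f = freqs.size
    S = np.zeros((n_f, n_ch, n_ch), dtype=complex)
    scale = 2.0 / fs  # one-sided density; unit-energy tapers
    for start in range(0, n_win, chunk):
        block = windows[start : start + chunk]  # (w, c, n)
        tapered = block[:, :, None, :] * tapers[None, None, :, :]  # (w, c, k, n)
        X = np.fft.rfft(tapered, axis=-1)[..., sel]  # (w, c, k, f)
        S += np.einsum("wckf,wdkf->fcd", X, np.conj(X))
    S *= scale / (n_win * n_tap)
    return freqs, S


def trial_band_power(
    segment: np.ndarray,
    band: tuple[float, float],
    spec: MultitaperSpec,
    fs: float,
) -> float:
    """Multitaper PSD of one segment, averaged over bins inside ``band``.

    Returns power in (unit)^2/Hz. An all-zero segment returns 0.0 (the
    caller must treat a zero as unusable before log-transforming).
    """
    segment = np.asarray(segment, dtype=float).reshape(-1)
    out = band_power_matrix(segment[None, None, :], band, spec, fs)
    return float(out[0, 0])


def band_power_matrix(
    segments: np.ndarray,
    band: tuple[float, float],
    spec: MultitaperSpec,
    fs: float,
    chunk: int = 2048,
) -> np.ndarray:
    """Band-averaged multitaper power for a stack of segments.

    Parameters
    ----------
    segments : ndarray, shape (n_trials, n_channels, n_samples)

    Returns
    -------
    ndarray, shape (n_trials, n_channels)
    """
    segments = np.asarray(segments, dtype=float)
    if segments.ndim != 3:
        raise ValueError("segments must be (n_trials, n_channels, n_samples)")
    n_tr, n_ch, n_samp = segments.shape
    fmin, fmax = band
    if not 0 < fmin < fmax:
        raise ValueError(f"invalid band ({fmin}, {fmax})")
    tapers = dpss_tapers(n_samp, spec)
    freqs = _freqs(n_samp, fs)
    sel = (freqs >= fmin) & (freqs <= fmax)
    if not sel.any():
        raise ValueError(f"no frequency bins inside [{fmin}, {fmax}] Hz")
    flat = segments.reshape(n_tr * n_ch, n_samp)
    out = np.empty(n_tr * n_ch)
    scale = 2.0 / fs
    n_tap = tapers.shape[0]
    sel_idx = np.flatnonzero(sel)
    # narrow bands: evaluate the DFT only at the needed bins (same math as
    # the rfft path, bin for bin)
    use_direct = sel_idx.size * 4 < n_samp // 2
    if use_direct:
        ang = -2.0 * np.pi * np.outer(np.arange(n_samp), sel_idx) / n_samp
        F_cos, F_sin = np.cos(ang), np.sin(ang)  # (n_samp, n_bins)
    for start in range(0, flat.shape[0], chunk):
        block = flat[start : start + chunk]
        tapered = block[:, None, :] * tapers[None, :, :]  # (b, k, n)
        if use_direct:
            tf = tapered.reshape(-1, n_samp)
            sq = (tf @ F_cos) ** 2 + (tf @ F_sin) ** 2
            sq = sq.reshape(block.shape[0], n_tap, sel_idx.size)
        else:
            X = np.fft.rfft(tapered, axis=-1)[..., sel]
            sq = np.abs(X) ** 2
        psd = scale * np.mean(sq, axis=1)  # (b, f)
        out[start : start + block.shape[0]] = psd.mean(axis=-1)
    return out.reshape(n_tr, n_ch)
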