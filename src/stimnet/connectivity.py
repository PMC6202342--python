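"""Functional-network estimation.

Three kinds of electrode-by-electrode adjacency matrices are produced:

* **coherence** — magnitude-squared-free multitaper coherence
  ``C_xy(f) = |<S_xy>| / sqrt(<S_xx><S_yy>)`` with cross-spectra averaged
  over windows and tapers before normalization, then averaged over the
  frequency bins of a band (5–13 Hz for the low-frequency networks).
* **hfb_envelope** — Fisher-z-transformed correlation of the slow (<1 Hz)
  high-frequency-broadband (50–200 Hz) amplitude envelope, built from 15
  consecutive 10 Hz sub-bands.
* **distance_lin** — linearized Euclidean distance ``exp(-d/d_max)``; 1.0
  means zero separation.

Node strength (mean connection weight) serves as the hub score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .recording import Recording, notch_filter
from .spectral import MultitaperSpec, multitaper_cross_spectra

__all__ = [
    "AdjacencyMatrix",
    "coherence_network",
    "per_frequency_networks",
    "hfb_envelope_network",
    "distance_network",
    "node_strength",
]

LOW_FREQ_BAND = (5.0, 13.0)
HFB_SUBBANDS = [(lo, lo + 10.0) for lo in range(50, 200, 10)]  # 15 bands


@dataclass
class AdjacencyMatrix:
    """Symmetric electrode-by-electrode network with a masked diagonal."""

    values: np.ndarray
    method: str  # {"coherence", "hfb_envelope", "distance_lin"}
    band: tuple[float, float] | float | None = None
    n_windows: int = 0
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.array(self.values, dtype=float)  # own copy; diagonal gets masked
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("adjacency must be square")
        off = ~np.eye(v.shape[0], dtype=bool)
        if not np.allclose(
            np.where(off, v, 0.0), np.where(off, v.T, 0.0), equal_nan=True
        ):
            raise ValueError("adjacency must be symmetric")
        np.fill_diagonal(v, np.nan)  # diagonal undefined
        self.values = v
        offv = v[off]
        if offv.size and self.method == "coherence":
            if np.nanmin(offv) < -1e-12 or np.nanmax(offv) > 1 + 1e-12:
                raise ValueError("coherence values must lie in [0, 1]")
        if offv.size and self.method == "distance_lin":
            if np.nanmin(offv) <= 0 or np.nanmax(offv) > 1 + 1e-12:
                raise ValueError("linearized distances must lie in (0, 1]")
        if self.labels is not None:
            self.labels = list(self.labels)
            if len(self.labels) != v.shape[0]:
                raise ValueError("label count mismatch")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def row(self, node: int | str) -> np.ndarray:
        """Connection weights from one node to all others (self = NaN)."""
        return self.values[self._index(node)]

    def _index(self, node: int | str) -> int:
        if isinstance(node, str):
            if self.labels is None:
                raise ValueError("adjacency has no labels")
            return self.labels.index(node)
        return int(node)


def _coherence_from_spectra(S: np.ndarray) -> np.ndarray:
    """Per-frequency coherence matrices from averaged cross-spectra."""
    power = np.real(np.einsum("fcc->fc", S))
    denom = np.sqrt(power[:, :, None] * power[:, None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.abs(S) / denom


def coherence_network(
    baseline_windows: np.ndarray,
    spec: MultitaperSpec = MultitaperSpec(),
    fs: float = 1000.0,
    band: tuple[float, float] = LOW_FREQ_BAND,
    labels: list[str] | None = None,
    min_windows: int = 100,
) -> AdjacencyMatrix:
    """Band-averaged multitaper coherence network from baseline windows.

    Cross-spectra are averaged across all windows and tapers, normalized by
    the averaged power spectra, and the resulting per-bin coherence is
    averaged over bins whose centers fall inside ``band`` (endpoints
    inclusive).
    """
    n_win = np.asarray(baseline_windows).shape[0]
    if n_win < min_windows:
        warnings.warn(
            f"only {n_win} baseline windows (< {min_windows}); "
            "coherence estimates will be noisy",
            stacklevel=2,
        )
    freqs, S = multitaper_cross_spectra(baseline_windows, spec, fs, band[0], band[1])
    coh = _coherence_from_spectra(S).mean(axis=0)
    np.fill_diagonal(coh, np.nan)
    coh = np.clip(coh, 0.0, 1.0)
    return AdjacencyMatrix(coh, "coherence", band=tuple(band), n_windows=n_win, labels=labels)


def per_frequency_networks(
    baseline_windows: np.ndarray,
    spec: MultitaperSpec = MultitaperSpec(),
    fs: float = 1000.0,
    fmin: float = 4.0,
    fmax: float = 50.0,
    step: float = 1.0,
    labels: list[str] | None = None,
) -> list[AdjacencyMatrix]:
    """One coherence network per frequency (no band averaging).

    For 1-s windows the spectral bins fall on integer frequencies and each
    target frequency maps onto exactly one bin; otherwise the nearest bin
    is used.
    """
    freqs, S = multitaper_cross_spectra(
        baseline_windows, spec, fs, max(0.0, fmin - step), fmax + step
    )
    coh = _coherence_from_spectra(S)
    n_win = np.asarray(baseline_windows).shape[0]
    targets = np.arange(fmin, fmax + step / 2, step)
    out = []
    for f in targets:
        idx = int(np.argmin(np.abs(freqs - f)))
        m = np.clip(coh[idx], 0.0, 1.0)
        np.fill_diagonal(m, np.nan)
        out.append(
            AdjacencyMatrix(m, "coherence", band=float(f), n_windows=n_win, labels=labels)
        )
    return out


def _fir_zero_phase(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Zero-phase filtering with a symmetric odd-length FIR (centered conv)."""
    return sp_signal.fftconvolve(x, taps[None, :], mode="same", axes=-1)


def hfb_envelope_network(
    rest_recording: Recording,
    line_freq: float = 60.0,
    subbands: list[tuple[float, float]] | None = None,
    lowpass_hz: float = 1.0,
    labels: list[str] | None = None,
    edge_trim_s: float = 2.0,
) -> AdjacencyMatrix:
    """Fisher-z correlation network of the slow HFB amplitude envelope.

    The recording is notch filtered, band-passed in 10 Hz steps from 50 to
    200 Hz (zero-phase FIR), Hilbert transformed; each sub-band amplitude
    is normalized by its own mean, sub-bands are averaged, the result is
    low-pass filtered below ``lowpass_hz``, and all channel pairs are
    Pearson correlated. Off-diagonal values are Fisher z (arctanh).
    """
    fs = rest_recording.fs
    if subbands is None:
        subbands = HFB_SUBBANDS
    top = max(hi for _, hi in subbands)
    if fs <= 2 * top:
        raise ValueError(f"fs={fs} Hz too low for a {top} Hz band edge")
    if rest_recording.duration < 30:
        raise ValueError("rest recording shorter than 30 s")
    if rest_recording.duration < 240:
        warnings.warn(
            f"rest recording is {rest_recording.duration:.0f} s (< 240 s); "
            "envelope correlations will be noisy",
            stacklevel=2,
        )
    rec = notch_filter(rest_recording, line_freq)
    x = rec.samples
    n_bp = int(round(3.3 * fs / 4.0)) // 2 * 2 + 1  # ~4 Hz transition, Hamming
    env_sum = np.zeros_like(x)
    for lo, hi in subbands:
        taps = sp_signal.firwin(n_bp, [lo, hi], pass_zero=False, fs=fs)
        bp = _fir_zero_phase(x, taps)
        amp = np.abs(sp_signal.hilbert(bp, axis=-1))
        env_sum += amp / amp.mean(axis=-1, keepdims=True)
    env = env_sum / len(subbands)
    n_lp = int(round(3.3 * fs / lowpass_hz)) // 2 * 2 + 1
    lp_taps = sp_signal.firwin(n_lp, lowpass_hz, fs=fs)
    slow = _fir_zero_phase(env - env.mean(axis=-1, keepdims=True), lp_taps)
    trim = int(round(edge_trim_s * fs))
    if slow.shape[1] > 4 * trim:
        slow = slow[:, trim:-trim]
    r = np.corrcoef(slow)
    np.fill_diagonal(r, np.nan)
    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    return AdjacencyMatrix(
        z,
        "hfb_envelope",
        band=(float(subbands[0][0]), float(subbands[-1][1])),
        n_windows=rec.n_samples,
        labels=labels if labels is not None else list(rest_recording.labels),
    )


def distance_network(layout, normalize: str = "max") -> AdjacencyMatrix:
    """Linearized pairwise Euclidean distance, ``exp(-d_normalized)``.

    Distances are normalized by the layout's maximum pairwise distance
    (``normalize="max"``, default, dimensionless in (0, 1]) or left in raw
    mm (``normalize="none"``). Zero separation maps to exactly 1.0.
    """
    coords = np.asarray(layout.coordinates, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 electrodes for a distance network")
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0):
        warnings.warn("coincident electrodes: distance 0 between distinct labels")
    if normalize == "max":
        dmax = d[off].max()
        if dmax == 0:
            dmax = 1.0
        d = d / dmax
    elif normalize != "none":
        raise ValueError(f"unknown normalization {normalize!r}")
    vals = np.exp(-d)
    np.fill_diagonal(vals, np.nan)
    return AdjacencyMatrix(
        vals, "distance_lin", band=None, n_windows=0, labels=list(layout.labels)
    )


def node_strength(adj: AdjacencyMatrix, node: int | str | None = None):
    """Normalized node strength: mean off-diagonal weight, in [0, 1] for
    coherence networks.

    With ``node=None`` returns the strength of every node.
    """
    n = adj.n_nodes
    if n < 2:
        raise ValueError("node strength undefined for a single-node network")
    sums = np.nansum(adj.values, axis=1) / (n - 1)
    if node is None:
        return sums
    return float(sums[adj._index(node)])
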