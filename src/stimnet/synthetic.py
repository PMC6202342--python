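"""Synthetic studies with known ground truth.

Every downstream stage of the pipeline can be validated against data whose
generating parameters are known exactly:

* **Layouts** emulate depth-electrode geometry (contacts at least 3.5 mm
  apart in a 60 x 60 x 40 mm volume) with per-electrode white-matter
  distances and clinical flags.
* **Baseline recordings** plant 5–13 Hz coherence structure via shared
  narrowband latent sources: each source is a sinusoid whose phase is
  re-randomized every 10 s period, mixed into channels plus independent
  white noise. Channel pairs sharing a source are coherent at that
  source's frequency; pairs sharing none sit at the estimator's bias
  floor.
* **Stimulation sessions** plant the effect the NMA regression must
  recover, directly at the level the pipeline measures: per-trial log
  theta power is drawn Normal with a post-window mean shift
  ``delta_e = beta0 + beta_conn * logit(coherence) + beta_dist *
  distance_lin``, and each 900 ms segment is a fixed theta carrier scaled
  so its multitaper theta power equals the drawn value exactly.
* **Artifacts** add a DC offset and/or variance inflation to the 350 ms
  post-stimulation screening windows of selected channels.
* **HFB rest recordings** give channel groups a shared slow (<1 Hz)
  amplitude modulation on independent broadband carriers.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import AdjacencyMatrix, coherence_network, distance_network
from .nma import logit
from .recording import ElectrodeLayout, Recording, StimSession, cut_windows
from .spectral import MultitaperSpec, trial_band_power

__all__ = [
    "GroundTruth",
    "SyntheticStudy",
    "make_ground_truth",
    "generate_layout",
    "generate_baseline",
    "generate_stim_session",
    "simulate_log_power_trials",
    "inject_artifact",
    "generate_hfb_rest",
    "generate_study",
]

THETA_BAND = (5.0, 8.0)
STIM_DURATION_S = 0.5
INTER_TRIAL_S = 3.5
AMPLITUDE_LEVELS_MA = (0.5, 1.0, 1.5)
PULSE_FREQS_HZ = (10.0, 25.0, 50.0, 100.0, 200.0)


@dataclass
class GroundTruth:
    """Planted parameters of a synthetic study.

    beta0 / beta_conn / beta_dist act on mean log theta power (natural-log
    units): per electrode, the post-stimulation shift is
    ``beta0 + beta_conn * logit(coherence to stim site) + beta_dist *
    linearized distance``. ``noise_sd`` is the trialwise SD of log power.
    """

    mixing_weights: np.ndarray  # (n_sources, n_channels)
    source_freqs: np.ndarray  # Hz
    beta0: float = 0.05
    beta_conn: float = 0.02
    beta_dist: float = 0.1
    noise_sd: float = 0.2
    artifact_channels: tuple[int, ...] = ()
    artifact_offset_uv: float = 50.0
    artifact_var_factor: float = 1.0
    envelope_coupling: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.mixing_weights = np.atleast_2d(np.asarray(self.mixing_weights, dtype=float))
        self.source_freqs = np.atleast_1d(np.asarray(self.source_freqs, dtype=float))
        if self.mixing_weights.shape[0] != self.source_freqs.size:
            raise ValueError("one frequency per latent source required")
        if not np.all(np.isfinite(self.mixing_weights)):
            raise ValueError("mixing weights must be finite")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.artifact_var_factor < 1:
            raise ValueError("artifact_var_factor must be >= 1")
        if self.envelope_coupling is not None:
            c = np.asarray(self.envelope_coupling, dtype=float)
            if (
                c.ndim != 2
                or c.shape[0] != c.shape[1]
                or not np.allclose(c, c.T)
                or not np.allclose(np.diag(c), 1.0)
                or c.min() < 0
                or c.max() > 1
            ):
                raise ValueError("envelope_coupling must be symmetric in [0,1] with unit diagonal")
            self.envelope_coupling = c

    @property
    def n_channels(self) -> int:
        return self.mixing_weights.shape[1]


@dataclass
class SyntheticStudy:
    layout: ElectrodeLayout
    baseline: Recording
    sessions: list[StimSession]
    truth: GroundTruth
    coherence: AdjacencyMatrix | None = None
    distance: AdjacencyMatrix | None = None

    def __post_init__(self) -> None:
        n = self.layout.n_electrodes
        if self.baseline.n_channels != n:
            raise ValueError("baseline channel count differs from layout")
        for s in self.sessions:
            if s.n_channels != n:
                raise ValueError("session channel count differs from layout")


def generate_layout(
    n_electrodes: int,
    seed: int,
    min_spacing_mm: float = 3.5,
    box_mm: tuple[float, float, float] = (60.0, 60.0, 40.0),
    frac_soz: float = 0.1,
    frac_spiking: float = 0.05,
    frac_in_wm: float = 0.1,
    wm_distance_max_mm: float = 10.0,
) -> ElectrodeLayout:
    """Random electrode layout with a minimum pairwise separation.

    Coordinates are sampled uniformly inside a box with rejection until all
    pairs are at least ``min_spacing_mm`` apart (matching real contact
    spacing of 3.5–10 mm); white-matter distances are Uniform(0, 10) mm.
    Virtual electrode i is the bipolar pair of physical contacts
    (C{i}, C{i+1}), so consecutive electrodes share a contact.
    """
    if n_electrodes < 1:
        raise ValueError("n_electrodes must be >= 1")
    rng = np.random.default_rng(seed)
    box = np.asarray(box_mm, dtype=float)
    coords: list[np.ndarray] = []
    attempts = 0
    while len(coords) < n_electrodes:
        p = rng.uniform(0, 1, size=3) * box
        if all(np.linalg.norm(p - q) >= min_spacing_mm for q in coords):
            coords.append(p)
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not place electrodes with the requested spacing")
    coords_arr = np.array(coords)
    n_soz = int(round(frac_soz * n_electrodes))
    n_spk = int(round(frac_spiking * n_electrodes))
    n_wm = int(round(frac_in_wm * n_electrodes))
    perm = rng.permutation(n_electrodes)
    soz = np.zeros(n_electrodes, dtype=bool)
    spiking = np.zeros(n_electrodes, dtype=bool)
    in_wm = np.zeros(n_electrodes, dtype=bool)
    soz[perm[:n_soz]] = True
    spiking[perm[n_soz : n_soz + n_spk]] = True
    in_wm[perm[n_soz + n_spk : n_soz + n_spk + n_wm]] = True
    wm_distance = rng.uniform(0, wm_distance_max_mm, size=n_electrodes)
    labels = [f"C{i}-C{i + 1}" for i in range(n_electrodes)]
    members = [(f"C{i}", f"C{i + 1}") for i in range(n_electrodes)]
    return ElectrodeLayout(
        labels=labels,
        coordinates=coords_arr,
        soz=soz,
        spiking=spiking,
        wm_distance=wm_distance,
        in_wm=in_wm,
        contact_members=members,
    )


def make_ground_truth(
    n_channels: int,
    seed: int = 0,
    n_sources: int | None = None,
    channels_per_source: int = 12,
    snr: float = 2.0,
    channel_noise_sd: float = 1.0,
    **overrides,
) -> GroundTruth:
    """Ground truth with a block mixing matrix sized for a target SNR.

    Source s loads onto a contiguous block of channels with random weights
    scaled so that each loaded channel's source-to-noise variance ratio is
    ``snr``. Source frequencies are spread across 6–12 Hz.
    """
    rng = np.random.default_rng(seed)
    if n_sources is None:
        n_sources = max(2, n_channels // channels_per_source)
    mixing = np.zeros((n_sources, n_channels))
    step = max(1, n_channels // n_sources)
    for s in range(n_sources):
        start = s * step
        idx = np.arange(start, min(start + channels_per_source, n_channels))
        # sinusoid of unit amplitude has variance 1/2: w^2/2 = snr * sd^2
        base = np.sqrt(2 * snr) * channel_noise_sd
        mixing[s, idx] = base * rng.uniform(0.8, 1.2, size=idx.size)
    freqs = np.linspace(6.0, 12.0, n_sources)
    return GroundTruth(
        mixing_weights=mixing, source_freqs=freqs, seed=seed, **overrides
    )


def generate_baseline(
    layout: ElectrodeLayout,
    truth: GroundTruth,
    n_periods: int = 10,
    period_s: float = 10.0,
    fs: float = 1000.0,
    seed: int = 0,
    channel_noise_sd: float = 1.0,
) -> Recording:
    """Baseline recording with planted narrowband coherence structure.

    Each channel is a weighted sum of narrowband sources (sinusoids whose
    phases are re-randomized every period, making windows from different
    periods independent) plus independent white noise.
    """
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    if np.any(truth.source_freqs >= fs / 2):
        raise ValueError("source frequency at or above Nyquist")
    if truth.n_channels != layout.n_electrodes:
        raise ValueError("ground truth channel count differs from layout")
    rng = np.random.default_rng(seed)
    n_per = int(round(period_s * fs))
    t = np.arange(n_per) / fs
    n_src, n_ch = truth.mixing_weights.shape
    out = np.empty((n_ch, n_periods * n_per))
    for p in range(n_periods):
        phases = rng.uniform(0, 2 * np.pi, size=n_src)
        sources = np.sin(
            2 * np.pi * truth.source_freqs[:, None] * t[None, :] + phases[:, None]
        )
        seg = truth.mixing_weights.T @ sources
        seg += rng.normal(0, channel_noise_sd, size=seg.shape)
        out[:, p * n_per : (p + 1) * n_per] = seg
    return Recording(out, fs, list(layout.labels), montage="bipolar")


def _resolve_stim_index(layout: ElectrodeLayout, stim_pair) -> tuple[int, tuple[str, str]]:
    if isinstance(stim_pair, str):
        idx = layout.index(stim_pair)
    else:
        pair = tuple(stim_pair)
        if layout.contact_members is not None and pair in [
            tuple(m) for m in layout.contact_members
        ]:
            idx = [tuple(m) for m in layout.contact_members].index(pair)
        elif "-".join(pair) in layout.labels:
            idx = layout.index("-".join(pair))
        else:
            raise KeyError(f"stimulation pair {pair!r} not found in layout")
    members = (
        tuple(layout.contact_members[idx])
        if layout.contact_members is not None
        else (layout.labels[idx], layout.labels[idx])
    )
    return idx, members


def planted_deltas(
    truth: GroundTruth,
    coherence: AdjacencyMatrix,
    distance: AdjacencyMatrix,
    stim_idx: int,
) -> np.ndarray:
    """Per-electrode post-stimulation shift in mean log theta power."""
    n = coherence.n_nodes
    conn = coherence.values[stim_idx].copy()
    dist = distance.values[stim_idx].copy()
    delta = np.zeros(n)
    mask = np.arange(n) != stim_idx
    delta[mask] = (
        truth.beta0
        + truth.beta_conn * logit(np.clip(conn[mask], 0.0, 1.0))
        + truth.beta_dist * dist[mask]
    )
    return delta


def simulate_log_power_trials(
    truth: GroundTruth,
    coherence: AdjacencyMatrix,
    distance: AdjacencyMatrix,
    stim_idx: int,
    n_trials: int = 240,
    seed: int | None = None,
    baseline_log_power: float = float(np.log(100.0)),
    between_electrode_sd: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw per-trial pre/post log theta power under the planted model.

    Returns (pre_log, post_log, delta) with shapes (n_trials, n_channels),
    (n_trials, n_channels), (n_channels,). These are exactly the log
    powers that segment synthesis reproduces at the multitaper level, so
    the power contrast and NMA chain can run directly from them.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_ch = coherence.n_nodes
    delta = planted_deltas(truth, coherence, distance, stim_idx)
    mu = baseline_log_power + rng.normal(0, between_electrode_sd, size=n_ch)
    pre_log = rng.normal(mu[None, :], truth.noise_sd, size=(n_trials, n_ch))
    post_log = rng.normal(
        (mu + delta)[None, :], truth.noise_sd, size=(n_trials, n_ch)
    )
    return pre_log, post_log, delta


def _theta_carrier(fs: float, spec: MultitaperSpec) -> tuple[np.ndarray, float]:
    """Fixed theta-band sinusoid and its multitaper theta power."""
    n = int(round(0.9 * fs))
    k = int(round(6.5 * n / fs))  # bin-centered frequency near 6.5 Hz
    carrier = np.sin(2 * np.pi * k * np.arange(n) / n)
    p0 = trial_band_power(carrier, THETA_BAND, spec, fs)
    return carrier, p0


def generate_stim_session(
    layout: ElectrodeLayout,
    coherence: AdjacencyMatrix,
    distance: AdjacencyMatrix,
    truth: GroundTruth,
    stim_pair,
    n_trials: int = 240,
    fs: float = 1000.0,
    seed: int | None = None,
    spec: MultitaperSpec = MultitaperSpec(),
    artifact_noise_uv: float = 20.0,
) -> StimSession:
    """Trial-cut stimulation session realizing the planted power model.

    Each 900 ms power window is a fixed theta carrier scaled so that its
    multitaper theta power equals the drawn log-power value exactly
    (power scales quadratically with amplitude, so the match is exact for
    any quadratic estimator). The 350 ms artifact-screening windows are
    white noise; use :func:`inject_artifact` to contaminate channels.
    """
    stim_idx, members = _resolve_stim_index(layout, stim_pair)
    rng = np.random.default_rng(seed)
    pre_log, post_log, _ = simulate_log_power_trials(
        truth, coherence, distance, stim_idx, n_trials=n_trials, rng=rng
    )
    carrier, p0 = _theta_carrier(fs, spec)
    pre = np.sqrt(np.exp(pre_log) / p0)[:, :, None] * carrier[None, None, :]
    post = np.sqrt(np.exp(post_log) / p0)[:, :, None] * carrier[None, None, :]
    n_art = int(round(0.35 * fs))
    n_ch = layout.n_electrodes
    pre_art = rng.normal(0, artifact_noise_uv, size=(n_trials, n_ch, n_art))
    post_art = rng.normal(0, artifact_noise_uv, size=(n_trials, n_ch, n_art))
    onsets = 5.0 + INTER_TRIAL_S * np.arange(n_trials)
    block = 60
    amplitudes = np.array(
        [AMPLITUDE_LEVELS_MA[(i // block) % len(AMPLITUDE_LEVELS_MA)] for i in range(n_trials)]
    )
    freqs = np.empty(n_trials)
    for start in range(0, n_trials, block):
        size = min(block, n_trials - start)
        reps = np.tile(PULSE_FREQS_HZ, int(np.ceil(size / len(PULSE_FREQS_HZ))))[:size]
        freqs[start : start + size] = rng.permutation(reps)
    return StimSession(
        stim_pair=members,
        onsets=onsets,
        stim_duration=STIM_DURATION_S,
        amplitudes=amplitudes,
        pulse_freqs=freqs,
        fs=fs,
        labels=list(layout.labels),
        pre=pre,
        post=post,
        pre_art=pre_art,
        post_art=post_art,
    )


def inject_artifact(
    session: StimSession,
    channels,
    offset_uv: float,
    var_factor: float = 1.0,
) -> StimSession:
    """Contaminate post-stimulation screening windows of selected channels.

    Adds a DC offset and scales the within-window variance (about each
    trial's own mean) by ``var_factor``. With offset 0 and var_factor 1
    the returned session is bit-identical to the input.
    """
    idx = []
    for c in channels:
        if isinstance(c, str):
            if c not in session.labels:
                raise KeyError(f"unknown channel {c!r}")
            idx.append(session.labels.index(c))
        else:
            if not 0 <= int(c) < session.n_channels:
                raise IndexError(f"channel index {c} out of range")
            idx.append(int(c))
    out = session.copy()
    if offset_uv == 0 and var_factor == 1:
        return out
    seg = out.post_art[:, idx, :]
    # center on the per-channel mean across all trials so the scaling
    # inflates trial-to-trial variability (what the Levene screen sees)
    mean = seg.mean(axis=(0, 2), keepdims=True)
    out.post_art[:, idx, :] = mean + (seg - mean) * np.sqrt(var_factor) + offset_uv
    return out


def generate_hfb_rest(
    n_channels: int,
    groups: list[list[int]],
    duration_s: float = 240.0,
    fs: float = 1000.0,
    seed: int = 0,
    mod_depth: float = 0.5,
    mod_band_hz: tuple[float, float] = (0.05, 0.5),
    carrier_band_hz: tuple[float, float] = (50.0, 200.0),
    labels: list[str] | None = None,
) -> Recording:
    """Rest recording with co-modulated high-frequency broadband amplitude.

    Channels in the same group share one slow random amplitude envelope
    (band-limited noise in ``mod_band_hz``, normalized to unit SD) applied
    at depth ``mod_depth`` to otherwise independent broadband carriers.
    """
    from scipy import signal as sp_signal

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    sos = sp_signal.butter(4, carrier_band_hz, btype="bandpass", fs=fs, output="sos")
    group_of = {}
    for g, members in enumerate(groups):
        for c in members:
            group_of[int(c)] = g

    def band_limited_noise() -> np.ndarray:
        # spectral synthesis: exact band limits, no filter edge transients
        # (time-domain IIR filtering is ill-conditioned at <<1 Hz corners)
        spectrum = np.fft.rfft(rng.normal(0, 1, size=n))
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        spectrum[(freqs < mod_band_hz[0]) | (freqs > mod_band_hz[1])] = 0.0
        s = np.fft.irfft(spectrum, n)
        return s / s.std()

    slow = {g: band_limited_noise() for g in range(len(groups))}
    x = np.empty((n_channels, n))
    for c in range(n_channels):
        carrier = sp_signal.sosfiltfilt(sos, rng.normal(0, 1, size=n))
        if c in group_of:
            env = 1.0 + mod_depth * slow[group_of[c]]
            env = np.clip(env, 0.05, None)
            x[c] = carrier * env
        else:
            x[c] = carrier
    if labels is None:
        labels = [f"H{c}" for c in range(n_channels)]
    return Recording(x, fs, labels, montage="bipolar")


def generate_study(
    n_electrodes: int = 60,
    n_sites: int = 3,
    n_trials: int = 240,
    n_baseline_periods: int = 10,
    fs: float = 1000.0,
    seed: int = 0,
    truth: GroundTruth | None = None,
    spec: MultitaperSpec = MultitaperSpec(),
    apply_artifacts: bool = True,
) -> SyntheticStudy:
    """Full synthetic study: layout, baseline, estimated networks, sessions.

    The baseline is generated first and its 5–13 Hz coherence network
    estimated; stimulation sessions then plant the connectivity -> power
    effect on that estimated network, so the downstream regression sees
    exactly the predictors the effect was built from.
    """
    rng = np.random.default_rng(seed)
    layout = generate_layout(n_electrodes, seed=int(rng.integers(2**31 - 1)))
    if truth is None:
        truth = make_ground_truth(n_electrodes, seed=int(rng.integers(2**31 - 1)))
    baseline = generate_baseline(
        layout, truth, n_periods=n_baseline_periods, fs=fs,
        seed=int(rng.integers(2**31 - 1)),
    )
    coh = coherence_network(
        cut_windows(baseline, 1.0), spec, fs=fs, labels=list(layout.labels)
    )
    dist = distance_network(layout)
    candidates = np.flatnonzero(~(layout.soz | layout.spiking))
    sites = rng.choice(candidates, size=min(n_sites, candidates.size), replace=False)
    sessions = []
    for s in sites:
        sess = generate_stim_session(
            layout, coh, dist, truth, layout.labels[int(s)],
            n_trials=n_trials, fs=fs, seed=int(rng.integers(2**31 - 1)), spec=spec,
        )
        if apply_artifacts and truth.artifact_channels:
            sess = inject_artifact(
                sess,
                list(truth.artifact_channels),
                truth.artifact_offset_uv,
                truth.artifact_var_factor,
            )
        sessions.append(sess)
    return SyntheticStudy(
        layout=layout,
        baseline=baseline,
        sessions=sessions,
        truth=truth,
        coherence=coh,
        distance=dist,
    )
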