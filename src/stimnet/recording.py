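"""In-memory containers and preprocessing for intracranial recordings.

The unit of analysis is the *virtual electrode*: the difference of two
adjacent physical contacts (bipolar montage), which removes activity on the
shared reference. Stimulation sessions are represented by the four
per-trial windows the analysis needs — a 900 ms pre/post window for
spectral power and a 350 ms pre/post window flanking the stimulation
interval for voltage-artifact screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sp_signal
from scipy import stats

from .errors import TooFewElectrodesError

__all__ = [
    "Recording",
    "ElectrodeLayout",
    "StimSession",
    "ChannelMask",
    "bipolar_rereference",
    "notch_filter",
    "extract_trial_windows",
    "cut_windows",
    "detect_artifact_channels",
    "apply_exclusions",
]

#: window extents, seconds, relative to stimulation onset/offset
PRE_POWER_OFFSET = (-0.950, -0.050)
POST_POWER_OFFSET = (0.050, 0.950)  # relative to stimulation *offset*
ARTIFACT_WINDOW_S = 0.350


@dataclass
class Recording:
    """Multichannel voltage time series.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltage in microvolts.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Unique channel names, one per row of ``samples``.
    montage : {"monopolar", "bipolar"}
    """

    samples: np.ndarray
    fs: float
    labels: list[str]
    montage: str = "monopolar"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        self.labels = list(self.labels)
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError("label count does not match channel count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.montage not in ("monopolar", "bipolar"):
            raise ValueError(f"unknown montage {self.montage!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class ElectrodeLayout:
    """Per-(virtual)-electrode metadata: geometry and clinical flags.

    ``wm_distance`` is the distance (mm) from the bipolar midpoint to the
    nearest white-matter surface vertex; ``in_wm`` is an expert label that a
    contact sits within white matter and takes precedence over any
    distance-based categorization. ``contact_members`` names the two
    physical contacts forming each virtual electrode and drives the
    shares-a-stimulated-contact exclusion.
    """

    labels: list[str]
    coordinates: np.ndarray  # (n, 3) mm
    soz: np.ndarray  # bool
    spiking: np.ndarray  # bool
    wm_distance: np.ndarray  # mm, >= 0
    in_wm: np.ndarray  # bool, expert label
    contact_members: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        n = len(self.labels)
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(n, 3)
        self.soz = np.asarray(self.soz, dtype=bool).reshape(n)
        self.spiking = np.asarray(self.spiking, dtype=bool).reshape(n)
        self.wm_distance = np.asarray(self.wm_distance, dtype=float).reshape(n)
        self.in_wm = np.asarray(self.in_wm, dtype=bool).reshape(n)
        if np.any(self.wm_distance < 0):
            raise ValueError("white-matter distances must be non-negative")
        if self.contact_members is not None:
            if len(self.contact_members) != n:
                raise ValueError("contact_members length mismatch")
            self.contact_members = [tuple(p) for p in self.contact_members]

    @property
    def n_electrodes(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class StimSession:
    """Trial-cut stimulation session.

    Arrays are (n_trials, n_channels, n_window_samples): ``pre``/``post``
    are the 900 ms spectral-power windows, ``pre_art``/``post_art`` the
    350 ms artifact-screening windows abutting the stimulation interval.
    """

    stim_pair: tuple[str, str]
    onsets: np.ndarray  # seconds
    stim_duration: float  # seconds
    amplitudes: np.ndarray  # mA per trial
    pulse_freqs: np.ndarray  # Hz per trial
    fs: float
    labels: list[str]
    pre: np.ndarray
    post: np.ndarray
    pre_art: np.ndarray
    post_art: np.ndarray

    def __post_init__(self) -> None:
        self.stim_pair = tuple(self.stim_pair)
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.pulse_freqs = np.asarray(self.pulse_freqs, dtype=float)
        self.labels = list(self.labels)
        for name in ("pre", "post", "pre_art", "post_art"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.ndim != 3:
                raise ValueError(f"{name} must be 3-D (trials, channels, samples)")
        n_trials = self.pre.shape[0]
        if not (self.post.shape[0] == self.pre_art.shape[0] == self.post_art.shape[0] == n_trials):
            raise ValueError("trial counts differ between windows")
        if self.pre.shape[1] != len(self.labels):
            raise ValueError("channel count does not match labels")

    @property
    def n_trials(self) -> int:
        return self.pre.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pre.shape[1]

    def copy(self) -> "StimSession":
        return replace(
            self,
            onsets=self.onsets.copy(),
            amplitudes=self.amplitudes.copy(),
            pulse_freqs=self.pulse_freqs.copy(),
            labels=list(self.labels),
            pre=self.pre.copy(),
            post=self.post.copy(),
            pre_art=self.pre_art.copy(),
            post_art=self.post_art.copy(),
        )


@dataclass
class ChannelMask:
    """Inclusion mask with per-electrode exclusion reasons.

    ``reasons`` maps a channel label to the (nonempty) set of reasons it
    was excluded; included channels never appear in ``reasons``.
    """

    labels: list[str]
    included: np.ndarray  # bool
    reasons: dict[str, frozenset[str]] = field(default_factory=dict)

    VALID_REASONS = frozenset(
        {"artifact", "soz_or_spiking", "shares_stim_contact", "stim_site", "user"}
    )

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.included = np.asarray(self.included, dtype=bool).reshape(len(self.labels))
        self.reasons = {k: frozenset(v) for k, v in self.reasons.items()}
        excluded = {lab for lab, inc in zip(self.labels, self.included) if not inc}
        if set(self.reasons) != excluded:
            raise ValueError("reasons must be present exactly on excluded channels")
        if any(not v for v in self.reasons.values()):
            raise ValueError("excluded channels need at least one reason")
        for v in self.reasons.values():
            unknown = v - self.VALID_REASONS
            if unknown:
                raise ValueError(f"unknown exclusion reasons: {sorted(unknown)}")

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    def union(self, other: "ChannelMask") -> "ChannelMask":
        """Combine two masks over the same labels (exclusions accumulate)."""
        if self.labels != other.labels:
            raise ValueError("masks cover different channels")
        included = self.included & other.included
        reasons: dict[str, frozenset[str]] = {}
        for lab, inc in zip(self.labels, included):
            if not inc:
                reasons[lab] = self.reasons.get(lab, frozenset()) | other.reasons.get(
                    lab, frozenset()
                )
        return ChannelMask(self.labels, included, reasons)


def bipolar_rereference(recording: Recording, pairs: list[tuple[str, str]]) -> Recording:
    """Difference adjacent physical contacts into virtual electrodes.

    Output channel i is ``first - second`` of ``pairs[i]`` and is labelled
    ``"A-B"``. Any signal common to both contacts (the shared reference)
    cancels exactly.
    """
    if recording.montage != "monopolar":
        raise ValueError("input must be a monopolar recording")
    index = {lab: i for i, lab in enumerate(recording.labels)}
    rows = []
    labels = []
    for a, b in pairs:
        if a == b:
            raise ValueError(f"bipolar pair of identical contacts: {a!r}")
        for name in (a, b):
            if name not in index:
                raise KeyError(f"unknown contact {name!r}")
        rows.append(recording.samples[index[a]] - recording.samples[index[b]])
        labels.append(f"{a}-{b}")
    return Recording(np.array(rows), recording.fs, labels, montage="bipolar")


def notch_filter(recording: Recording, line_freq: float = 60.0, q: float = 30.0) -> Recording:
    """Remove line noise with a zero-phase IIR notch at ``line_freq``."""
    if recording.fs <= 2 * line_freq:
        raise ValueError(
            f"sampling rate {recording.fs} Hz cannot notch {line_freq} Hz (Nyquist)"
        )
    b, a = sp_signal.iirnotch(line_freq, q, fs=recording.fs)
    filtered = sp_signal.filtfilt(b, a, recording.samples, axis=-1)
    return Recording(filtered, recording.fs, list(recording.labels), recording.montage)


def _window_starts(onsets: np.ndarray, stim_duration: float, fs: float):
    """Sample start indices (0-based, half-open windows) for each trial."""
    onsets = np.asarray(onsets, dtype=float)
    pre = np.round((onsets + PRE_POWER_OFFSET[0]) * fs).astype(int)
    post = np.round((onsets + stim_duration + POST_POWER_OFFSET[0]) * fs).astype(int)
    pre_art = np.round((onsets - ARTIFACT_WINDOW_S) * fs).astype(int)
    post_art = np.round((onsets + stim_duration) * fs).astype(int)
    return pre, post, pre_art, post_art


def extract_trial_windows(
    recording: Recording,
    onsets: np.ndarray,
    stim_duration: float = 0.5,
    stim_pair: tuple[str, str] = ("?", "?"),
    amplitudes: np.ndarray | None = None,
    pulse_freqs: np.ndarray | None = None,
) -> StimSession:
    """Cut a continuous recording into per-trial analysis windows.

    Power windows span [-950, -50) ms before onset and [+50, +950) ms after
    stimulation offset; artifact windows are the 350 ms immediately before
    onset and immediately after offset. Trials whose windows fall outside
    the recording are dropped with a warning; zero surviving trials is an
    error.
    """
    fs = recording.fs
    onsets = np.asarray(onsets, dtype=float)
    n_pow = int(round(0.9 * fs))
    n_art = int(round(ARTIFACT_WINDOW_S * fs))
    pre_s, post_s, pre_a, post_a = _window_starts(onsets, stim_duration, fs)
    n_total = recording.n_samples
    ok = (
        (pre_a >= 0)
        & (pre_s >= 0)
        & (post_s + n_pow <= n_total)
        & (post_a + n_art <= n_total)
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} trial(s) with windows outside the recording",
            stacklevel=2,
        )
    if not ok.any():
        raise ValueError("no trial has all windows inside the recording")
    keep = np.flatnonzero(ok)
    samp = recording.samples

    def cut(starts: np.ndarray, length: int) -> np.ndarray:
        return np.stack([samp[:, s : s + length] for s in starts[keep]])

    if amplitudes is None:
        amplitudes = np.full(onsets.shape, np.nan)
    if pulse_freqs is None:
        pulse_freqs = np.full(onsets.shape, np.nan)
    return StimSession(
        stim_pair=tuple(stim_pair),
        onsets=onsets[keep],
        stim_duration=stim_duration,
        amplitudes=np.asarray(amplitudes, dtype=float)[keep],
        pulse_freqs=np.asarray(pulse_freqs, dtype=float)[keep],
        fs=fs,
        labels=list(recording.labels),
        pre=cut(pre_s, n_pow),
        post=cut(post_s, n_pow),
        pre_art=cut(pre_a, n_art),
        post_art=cut(post_a, n_art),
    )


def cut_windows(recording: Recording, window_s: float = 1.0) -> np.ndarray:
    """Sequential non-overlapping windows, shape (n_windows, n_channels, n)."""
    n = int(round(window_s * recording.fs))
    n_win = recording.n_samples // n
    if n_win == 0:
        raise ValueError("recording shorter than one window")
    trimmed = recording.samples[:, : n_win * n]
    return trimmed.reshape(recording.n_channels, n_win, n).transpose(1, 0, 2)


def detect_artifact_channels(
    session: StimSession,
    alpha: float = 0.01,
    levene_center: str = "median",
) -> ChannelMask:
    """Flag channels contaminated by a post-stimulation voltage artifact.

    Per channel, the trialwise mean voltage in the 350 ms before onset is
    compared with the 350 ms after offset by (i) a paired t-test on the
    means and (ii) a Levene test (Brown–Forsythe, median-centred, by
    default) for a variance change. Either test at P < ``alpha`` excludes
    the channel.
    """
    if session.n_trials < 2:
        raise ValueError("artifact detection needs at least 2 trials")
    pre_means = session.pre_art.mean(axis=2)  # (trials, channels)
    post_means = session.post_art.mean(axis=2)
    included = np.ones(session.n_channels, dtype=bool)
    reasons: dict[str, frozenset[str]] = {}
    for c, lab in enumerate(session.labels):
        p_t = stats.ttest_rel(pre_means[:, c], post_means[:, c]).pvalue
        p_lev = stats.levene(pre_means[:, c], post_means[:, c], center=levene_center).pvalue
        if (np.isfinite(p_t) and p_t < alpha) or (np.isfinite(p_lev) and p_lev < alpha):
            included[c] = False
            reasons[lab] = frozenset({"artifact"})
    return ChannelMask(list(session.labels), included, reasons)


def apply_exclusions(
    layout: ElectrodeLayout,
    artifact_mask: ChannelMask | None,
    stim_pair: tuple[str, str],
    min_electrodes: int = 10,
) -> ChannelMask:
    """Union all exclusion rules into a single channel mask.

    Excluded: artifact channels; SOZ or inter-ictally spiking electrodes;
    virtual electrodes sharing a physical contact with the stimulated pair;
    and the stimulated virtual electrode itself. Fewer than
    ``min_electrodes`` survivors is a hard error, mirroring the subject
    discard rule.
    """
    labels = list(layout.labels)
    if artifact_mask is not None and artifact_mask.labels != labels:
        raise ValueError("artifact mask does not align with layout")
    reasons: dict[str, set[str]] = {}
    stim_set = set(stim_pair)
    for i, lab in enumerate(labels):
        r: set[str] = set()
        if artifact_mask is not None and not artifact_mask.included[i]:
            r |= set(artifact_mask.reasons.get(lab, {"artifact"}))
        if layout.soz[i] or layout.spiking[i]:
            r.add("soz_or_spiking")
        members = (
            set(layout.contact_members[i]) if layout.contact_members is not None else {lab}
        )
        if members == stim_set or lab in stim_set or f"{stim_pair[0]}-{stim_pair[1]}" == lab:
            r.add("stim_site")
        elif members & stim_set:
            r.add("shares_stim_contact")
        if r:
            reasons[lab] = r
    included = np.array([lab not in reasons for lab in labels])
    if included.sum() < min_electrodes:
        raise TooFewElectrodesError(
            f"only {int(included.sum())} electrodes remain after exclusions "
            f"(minimum {min_electrodes})"
        )
    return ChannelMask(labels, included, {k: frozenset(v) for k, v in reasons.items()})
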