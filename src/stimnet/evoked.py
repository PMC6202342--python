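"""Stimulation-evoked band-power contrasts.

For each trial, multitaper power is computed in the 900 ms pre- and
post-stimulation windows; the natural-log powers are compared across trials
with a paired t-test, yielding one t-statistic per electrode per band.
No per-electrode p-values are attached: sequential trials are not
independent, so t-statistics are used only as inputs to later correlation
analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .recording import ChannelMask, StimSession
from .spectral import MultitaperSpec, band_power_matrix

__all__ = [
    "BandSpec",
    "BANDS",
    "PowerContrast",
    "power_contrast",
    "session_power_contrast",
    "whole_brain_power_change",
    "theta_responsive_subset",
]


@dataclass(frozen=True)
class BandSpec:
    name: str
    fmin: float
    fmax: float

    def __post_init__(self) -> None:
        if not 0 < self.fmin < self.fmax:
            raise ValueError(f"invalid band edges ({self.fmin}, {self.fmax})")

    @property
    def edges(self) -> tuple[float, float]:
        return (self.fmin, self.fmax)


#: analysis bands: theta 5-8, alpha/beta 10-25, gamma 30-50, HFB 50-200 Hz
BANDS: dict[str, BandSpec] = {
    "theta": BandSpec("theta", 5.0, 8.0),
    "alpha_beta": BandSpec("alpha_beta", 10.0, 25.0),
    "gamma": BandSpec("gamma", 30.0, 50.0),
    "hfb": BandSpec("hfb", 50.0, 200.0),
}


@dataclass
class PowerContrast:
    """Per-electrode paired t-statistics of pre vs post log band power."""

    t_stat: np.ndarray  # (n_electrodes,), NaN where undefined
    n_trials: int
    band: BandSpec
    labels: list[str] | None = None
    mask: ChannelMask | None = None
    zero_variance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t_stat = np.asarray(self.t_stat, dtype=float)
        if self.n_trials < 2:
            raise ValueError("need at least 2 trials")
        if self.zero_variance is None:
            self.zero_variance = np.zeros(self.t_stat.shape, dtype=bool)

    def included_indices(self) -> np.ndarray:
        """Indices usable in downstream analysis (mask-included, finite t)."""
        ok = np.isfinite(self.t_stat)
        if self.mask is not None:
            ok &= self.mask.included
        return np.flatnonzero(ok)


def power_contrast(
    pre_powers: np.ndarray,
    post_powers: np.ndarray,
    band: BandSpec = BANDS["theta"],
    labels: list[str] | None = None,
    mask: ChannelMask | None = None,
) -> PowerContrast:
    """Paired t-statistic of log post vs log pre power, per electrode.

    ``pre_powers`` and ``post_powers`` are (n_trials, n_electrodes) raw
    band powers; the contrast is computed on their natural logs. Electrodes
    whose trialwise log-power differences have zero variance get t = NaN
    and are flagged.
    """
    pre = np.asarray(pre_powers, dtype=float)
    post = np.asarray(post_powers, dtype=float)
    if pre.shape != post.shape or pre.ndim != 2:
        raise ValueError("pre and post power arrays must share (trials, electrodes) shape")
    n = pre.shape[0]
    if n < 2:
        raise ValueError("need at least 2 trials for a paired t-test")
    if np.any(pre <= 0) or np.any(post <= 0):
        raise ValueError("powers must be strictly positive to log-transform")
    d = np.log(post) - np.log(pre)
    sd = d.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d.mean(axis=0) / (sd / np.sqrt(n))
    t[zero_var] = np.nan
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} electrode(s) with zero-variance log-power "
            "difference; t undefined",
            stacklevel=2,
        )
    return PowerContrast(t, n, band, labels=labels, mask=mask, zero_variance=zero_var)


def session_power_contrast(
    session: StimSession,
    band: BandSpec = BANDS["theta"],
    spec: MultitaperSpec = MultitaperSpec(),
    mask: ChannelMask | None = None,
) -> PowerContrast:
    """Full path: multitaper band power of the trial windows, then contrast."""
    pre = band_power_matrix(session.pre, band.edges, spec, session.fs)
    post = band_power_matrix(session.post, band.edges, spec, session.fs)
    return power_contrast(pre, post, band=band, labels=list(session.labels), mask=mask)


def whole_brain_power_change(contrast: PowerContrast, t_ceiling: float = 10.0) -> float:
    """Mean t across included electrodes, excluding t > ``t_ceiling``.

    The ceiling guards the average against electrodes whose raw power is
    corrupted by residual stimulation artifact that survived screening.
    """
    idx = contrast.included_indices()
    t = contrast.t_stat[idx]
    t = t[t <= t_ceiling]
    if t.size == 0:
        raise ValueError("no electrodes remain for the whole-brain average")
    return float(t.mean())


def theta_responsive_subset(
    contrasts: dict[str, PowerContrast],
    threshold: float = 2.0,
    theta_key: str = "theta",
) -> dict[str, float]:
    """Mean t per higher band over electrodes with theta t strictly > threshold.

    Returns NaN per band when no electrode is theta-responsive (a flagged,
    non-contributing site, not an error).
    """
    if theta_key not in contrasts:
        raise KeyError("theta contrast required")
    theta = contrasts[theta_key]
    idx = theta.included_indices()
    responsive = idx[theta.t_stat[idx] > threshold]
    out: dict[str, float] = {}
    for name, con in contrasts.items():
        if name == theta_key:
            continue
        if responsive.size == 0:
            out[name] = float("nan")
        else:
            out[name] = float(np.nanmean(con.t_stat[responsive]))
    return out
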