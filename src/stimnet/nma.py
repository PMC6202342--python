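"""Network-mediated activation (NMA).

The central statistic: for one stimulation site, regress the per-electrode
evoked-power t-statistic on (i) logit-transformed functional connectivity
between the site and each recording electrode and (ii) linearized
Euclidean distance, with an intercept. The connectivity coefficient is
compared against a null distribution obtained by permuting the predictor
rows against the outcomes; its z-score relative to that null is the NMA,
and the two-tailed permutation p-value accompanies it.

Distance is included so that connectivity is only credited for structure
beyond the brain's tendency to connect (and co-activate) nearby regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .connectivity import AdjacencyMatrix
from .errors import RankDeficientDesignError, TooFewElectrodesError
from .evoked import BandSpec, PowerContrast

__all__ = ["NMAResult", "logit", "fit_regression", "permutation_null", "compute_nma"]

LOGIT_CLIP = 1e-6
MIN_ELECTRODES = 10


@dataclass
class NMAResult:
    """NMA for a single stimulation site."""

    beta_conn: float
    beta_dist: float
    intercept: float
    null_betas: np.ndarray
    z: float
    p_two_tailed: float
    n_electrodes: int
    n_perm: int
    seed: int | None
    band: BandSpec | None = None
    network_method: str | None = None
    stim_site: str | int | None = None


def logit(c, clip: float = LOGIT_CLIP):
    """``ln(c / (1 - c))`` for coherence values in (0, 1).

    Values touching 0 or 1 (possible for degenerate estimates) are clipped
    to [clip, 1 - clip] with a warning; values outside [0, 1] are an error.
    """
    arr = np.asarray(c, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("logit input must lie in [0, 1]")
    if np.any(arr <= 0) or np.any(arr >= 1):
        warnings.warn(
            f"coherence values at the [0, 1] boundary clipped to [{clip}, {1 - clip}]",
            stacklevel=2,
        )
        arr = np.clip(arr, clip, 1 - clip)
    out = np.log(arr / (1 - arr))
    return float(out) if np.isscalar(c) else out


def _design(conn_logit: np.ndarray, dist_lin: np.ndarray) -> np.ndarray:
    n = conn_logit.shape[0]
    return np.column_stack([np.ones(n), dist_lin, conn_logit])


def fit_regression(
    t_stats: np.ndarray,
    conn_logit: np.ndarray,
    dist_lin: np.ndarray,
    min_electrodes: int = MIN_ELECTRODES,
) -> tuple[float, float, float]:
    """OLS of t-statistics on (intercept, linearized distance, logit connectivity).

    Returns ``(intercept, beta_dist, beta_conn)``.
    """
    y = np.asarray(t_stats, dtype=float)
    conn = np.asarray(conn_logit, dtype=float)
    dist = np.asarray(dist_lin, dtype=float)
    if not (y.shape == conn.shape == dist.shape) or y.ndim != 1:
        raise ValueError("t_stats, conn_logit, dist_lin must be equal-length vectors")
    if y.size < min_electrodes:
        raise TooFewElectrodesError(
            f"regression needs >= {min_electrodes} electrodes, got {y.size}"
        )
    X = _design(conn, dist)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise RankDeficientDesignError("predictors are collinear (rank-deficient design)")
    return float(beta[0]), float(beta[1]), float(beta[2])


def permutation_null(
    t_stats: np.ndarray,
    conn_logit: np.ndarray,
    dist_lin: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    mode: str = "joint",
) -> np.ndarray:
    """Null distribution of the connectivity coefficient.

    Each draw permutes the predictor rows uniformly against the outcomes
    and refits the regression. ``mode="joint"`` (default) shuffles the
    (connectivity, distance) rows together, preserving their pairing;
    ``mode="connectivity"`` shuffles connectivity alone.
    """
    y = np.asarray(t_stats, dtype=float)
    conn = np.asarray(conn_logit, dtype=float)
    dist = np.asarray(dist_lin, dtype=float)
    n = y.size
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: z-score will be unstable", stacklevel=2)
    if mode not in ("joint", "connectivity"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    rng = np.random.default_rng(seed)
    # independent uniform permutations (argsort of iid uniforms), seeded
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    if mode == "joint":
        conn_p = conn[idx]
        dist_p = dist[idx]
    else:
        conn_p = conn[idx]
        dist_p = np.broadcast_to(dist, (n_perm, n))
    ones = np.ones((n_perm, n))
    # batched normal equations for X = [1, dist, conn]
    X = np.stack([ones, dist_p, conn_p], axis=-1)  # (P, n, 3)
    XtX = np.einsum("pni,pnj->pij", X, X)
    Xty = np.einsum("pni,n->pi", X, y)
    betas = np.linalg.solve(XtX, Xty[..., None])[..., 0]
    return betas[:, 2]


def compute_nma(
    contrast: PowerContrast,
    connectivity: AdjacencyMatrix,
    distance: AdjacencyMatrix,
    stim_site: int | str,
    n_perm: int = 1000,
    seed: int | None = None,
    mode: str = "joint",
    apply_logit: bool | None = None,
) -> NMAResult:
    """NMA z-score and permutation p-value for one stimulation site.

    Exclusions must already be recorded in ``contrast.mask``; the stim site
    itself is dropped if still present. Coherence values are logit
    transformed; Fisher-z envelope values (already unbounded) are used
    as-is unless ``apply_logit`` overrides the method-based default.

    p is the add-one-smoothed two-tailed permutation probability
    ``(1 + #{|null - mean| >= |beta - mean|}) / (n_perm + 1)``; z is
    ``(beta - mean(null)) / sd(null)`` with the n-1 sample SD.
    """
    site_idx = connectivity._index(stim_site)
    idx = contrast.included_indices()
    idx = idx[idx != site_idx]
    if idx.size < MIN_ELECTRODES:
        raise TooFewElectrodesError(
            f"{idx.size} electrodes after exclusions (minimum {MIN_ELECTRODES})"
        )
    conn_raw = connectivity.values[site_idx, idx]
    dist_lin = distance.values[site_idx, idx]
    if np.ptp(conn_raw) == 0:
        raise ValueError("degenerate connectivity: constant across electrodes")
    if apply_logit is None:
        apply_logit = connectivity.method == "coherence"
    conn = logit(conn_raw) if apply_logit else np.asarray(conn_raw, dtype=float)
    y = contrast.t_stat[idx]
    intercept, beta_dist, beta_conn = fit_regression(y, conn, dist_lin)
    null = permutation_null(y, conn, dist_lin, n_perm=n_perm, seed=seed, mode=mode)
    mu = null.mean()
    sd = null.std(ddof=1)
    z = (beta_conn - mu) / sd
    p = (1.0 + np.sum(np.abs(null - mu) >= abs(beta_conn - mu))) / (n_perm + 1.0)
    return NMAResult(
        beta_conn=beta_conn,
        beta_dist=beta_dist,
        intercept=intercept,
        null_betas=null,
        z=float(z),
        p_two_tailed=float(p),
        n_electrodes=int(idx.size),
        n_perm=n_perm,
        seed=seed,
        band=contrast.band,
        network_method=connectivity.method,
        stim_site=stim_site,
    )
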