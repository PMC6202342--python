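"""Site-level and group-level analyses.

Covers: white-matter categorization of stimulation sites and the ordered
trend permutation test; strongest/weakest-connected contrasts; hub
(node-strength) terciles; NMA-by-frequency profiles with BH-FDR; and the
directional count of individually significant sites against the binomial
false-positive expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectivity import AdjacencyMatrix
from .evoked import PowerContrast
from .nma import NMAResult, compute_nma, logit

__all__ = [
    "GroupResult",
    "StimSiteRecord",
    "classify_wm",
    "wm_trend_permutation_test",
    "ranked_connection_contrast",
    "hub_tercile_contrast",
    "nma_frequency_profile",
    "FrequencyProfile",
    "bh_fdr",
    "directional_count_test",
    "group_onesample_test",
    "moving_average",
]

WM_CATEGORIES = ("gray", "near", "in")


@dataclass
class GroupResult:
    test_name: str
    statistic: float
    p: float
    p_corrected: float | None = None
    n: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1) and np.isfinite(self.p):
            raise ValueError(f"p must lie in (0, 1], got {self.p}")
        if self.p_corrected is not None and self.p_corrected < self.p - 1e-12:
            raise ValueError("corrected p cannot be smaller than raw p")


@dataclass
class StimSiteRecord:
    """Everything the group analyses need about one stimulation site."""

    site_id: str
    wm_distance: float
    wm_category: str | None = None
    in_wm_label: bool = False
    nma: dict[tuple[str, str], NMAResult] = field(default_factory=dict)
    hub_score: float = float("nan")
    strongest5_mean_t: float = float("nan")
    weakest5_mean_t: float = float("nan")
    per_freq_nma: np.ndarray | None = None


def classify_wm(
    wm_distance: np.ndarray,
    in_wm: np.ndarray | None = None,
    direction: str = "near_is_close",
) -> np.ndarray:
    """Categorize stimulation sites as gray / near-white / in-white matter.

    Expert in-white-matter labels take precedence. Remaining sites are
    split at the median of their raw white-matter distances; with the
    default direction, distance <= median -> "near", > median -> "gray"
    (ties go to "near"). ``direction="near_is_far"`` inverts the split for
    the opposite reading of the percentile rule.
    """
    d = np.asarray(wm_distance, dtype=float)
    in_wm = (
        np.zeros(d.shape, dtype=bool) if in_wm is None else np.asarray(in_wm, dtype=bool)
    )
    rest = ~in_wm
    if rest.sum() < 2:
        raise ValueError("need at least 2 non-expert-labeled sites to split")
    med = np.median(d[rest])
    if np.all(d[rest] == med):
        warnings.warn("all white-matter distances equal: every split site -> 'near'")
    close = d <= med
    if direction == "near_is_close":
        near = close
    elif direction == "near_is_far":
        near = ~close
    else:
        raise ValueError(f"unknown direction {direction!r}")
    cats = np.where(near, "near", "gray").astype(object)
    cats[in_wm] = "in"
    return cats


def _safe_t_ind(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample (pooled) t of mean(a) - mean(b), defined at zero variance."""
    na, nb = a.size, b.size
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    pooled = ((na - 1) * va + (nb - 1) * vb) / max(na + nb - 2, 1)
    diff = a.mean() - b.mean()
    if pooled == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    se = np.sqrt(pooled * (1 / na + 1 / nb))
    return float(diff / se)


def _batched_min_t(vals: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """min(t(near vs gray), t(in vs near)) for each row of ``vals``.

    ``masks`` is the (3, n) indicator matrix in (gray, near, in) order.
    Pooled-variance two-sample t, defined as 0 (equal means) or signed
    infinity at zero pooled variance.
    """
    counts = masks.sum(axis=1)  # (3,)
    sums = vals @ masks.T  # (P, 3)
    sqs = (vals**2) @ masks.T
    means = sums / counts
    ss = sqs - counts * means**2  # within-group sum of squares
    out = np.empty((vals.shape[0], 2))
    for j, (a, b) in enumerate(((1, 0), (2, 1))):  # near-gray, in-near
        na, nb = counts[a], counts[b]
        dof = max(na + nb - 2, 1)
        pooled = (ss[:, a] + ss[:, b]) / dof
        pooled = np.maximum(pooled, 0.0)
        diff = means[:, a] - means[:, b]
        se = np.sqrt(pooled * (1 / na + 1 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / se
            degenerate = np.where(diff == 0, 0.0, np.sign(diff) * np.inf)
        t = np.where(se == 0, degenerate, t)
        out[:, j] = t
    return out.min(axis=1)


def wm_trend_permutation_test(
    nma_values: np.ndarray,
    categories: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> GroupResult:
    """Permutation test for an ordered gray < near < in trend.

    The statistic is ``min(t(near vs gray), t(in vs near))`` — both steps
    of the ordering must hold for the minimum to be large. Category labels
    are permuted across sites; p is the add-one-smoothed fraction of
    permutations whose min-t reaches the observed one.
    """
    values = np.asarray(nma_values, dtype=float)
    cats = np.asarray(categories, dtype=object)
    if values.shape != cats.shape:
        raise ValueError("values and categories must align")
    masks = np.array([cats == c for c in WM_CATEGORIES])
    if any(not m.any() for m in masks):
        raise ValueError("all three white-matter categories must be non-empty")
    observed = float(_batched_min_t(values[None, :], masks)[0])
    rng = np.random.default_rng(seed)
    # permuting labels over sites == permuting values against fixed masks
    idx = np.argsort(rng.random((n_perm, values.size)), axis=1)
    null = _batched_min_t(values[idx], masks)
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return GroupResult("wm_trend_permutation", observed, p, n=values.size)


def ranked_connection_contrast(
    contrast: PowerContrast,
    connectivity: AdjacencyMatrix,
    distance: AdjacencyMatrix,
    stim_site: int | str,
    k: int = 5,
) -> tuple[float, float]:
    """Mean evoked t at the k strongest vs k weakest connected electrodes.

    Connectivity (logit for coherence networks) is residualized on
    linearized distance (OLS with intercept) before ranking, so "strong"
    means strong beyond what proximity predicts.
    """
    site_idx = connectivity._index(stim_site)
    idx = contrast.included_indices()
    idx = idx[idx != site_idx]
    if idx.size < 2 * k:
        raise ValueError(f"need at least {2 * k} electrodes, got {idx.size}")
    conn_raw = connectivity.values[site_idx, idx]
    conn = logit(conn_raw) if connectivity.method == "coherence" else conn_raw
    dist = distance.values[site_idx, idx]
    X = np.column_stack([np.ones(idx.size), dist])
    beta, *_ = np.linalg.lstsq(X, conn, rcond=None)
    resid = conn - X @ beta
    order = np.argsort(resid)
    t = contrast.t_stat[idx]
    weak = float(t[order[:k]].mean())
    strong = float(t[order[-k:]].mean())
    return strong, weak


def _tercile_bins(n: int) -> tuple[int, int]:
    """Sizes of the low and high tercile; remainder goes to the middle bin."""
    low = n // 3
    return low, low


def hub_tercile_contrast(
    hub_scores: np.ndarray,
    strongest5_means: np.ndarray,
) -> GroupResult:
    """Weak-hub vs strong-hub contrast of evoked power at connected sites.

    Sites are binned into node-strength terciles by rank (remainders go to
    the middle bin); the statistic is the two-sample t of the
    strongest-five mean t between the weak-hub and strong-hub terciles
    (positive = weak hubs evoke more change).
    """
    hubs = np.asarray(hub_scores, dtype=float)
    vals = np.asarray(strongest5_means, dtype=float)
    n = hubs.size
    if n < 3 or vals.size != n:
        raise ValueError("need >= 3 sites with matching hub scores and contrasts")
    order = np.argsort(hubs, kind="stable")
    k_low, k_high = _tercile_bins(n)
    weak = vals[order[:k_low]]
    strong = vals[order[n - k_high :]]
    res = stats.ttest_ind(weak, strong)
    return GroupResult(
        "hub_tercile_contrast", float(res.statistic), float(res.pvalue), n=n
    )


def moving_average(x: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average with shrinking edges (display smoothing only)."""
    x = np.asarray(x, dtype=float)
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


@dataclass
class FrequencyProfile:
    freqs: np.ndarray  # (47,) Hz
    mean_nma: np.ndarray  # group mean z per frequency
    t_stats: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray
    smoothed: np.ndarray  # display curve only
    per_site_z: np.ndarray  # (n_sites, 47)


def nma_frequency_profile(
    site_inputs: list[tuple[PowerContrast, list[AdjacencyMatrix], AdjacencyMatrix, int | str]],
    n_perm: int = 1000,
    seed: int | None = None,
    smoothing: int = 3,
    alpha: float = 0.05,
) -> FrequencyProfile:
    """Group NMA as a function of the frequency of the coherence network.

    Each site supplies (contrast, per-frequency networks, distance
    network, stim site). The NMA is recomputed per site per network; a
    one-sample t against zero is run per frequency across sites, with
    BH-FDR over the frequency axis. Smoothing affects only the returned
    display curve, never the statistics.
    """
    if len(site_inputs) < 2:
        raise ValueError("need at least 2 sites")
    n_freq = len(site_inputs[0][1])
    if any(len(nets) != n_freq for _, nets, _, _ in site_inputs):
        raise ValueError("sites disagree on the number of per-frequency networks")
    rng = np.random.default_rng(seed)
    z = np.empty((len(site_inputs), n_freq))
    for i, (contrast, nets, dist, stim) in enumerate(site_inputs):
        for j, net in enumerate(nets):
            child = int(rng.integers(0, 2**31 - 1))
            z[i, j] = compute_nma(
                contrast, net, dist, stim, n_perm=n_perm, seed=child
            ).z
    freqs = np.array(
        [net.band if np.isscalar(net.band) else np.mean(net.band) for net in site_inputs[0][1]],
        dtype=float,
    )
    t_stats = np.empty(n_freq)
    p_raw = np.empty(n_freq)
    for j in range(n_freq):
        res = stats.ttest_1samp(z[:, j], 0.0)
        t_stats[j] = res.statistic
        p_raw[j] = res.pvalue
    p_adj, reject = bh_fdr(p_raw, q=alpha)
    mean_nma = z.mean(axis=0)
    return FrequencyProfile(
        freqs=freqs,
        mean_nma=mean_nma,
        t_stats=t_stats,
        p_raw=p_raw,
        p_adjusted=p_adj,
        significant=reject,
        smoothed=moving_average(mean_nma, smoothing),
        per_site_z=z,
    )


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: adjusted p-values and rejection mask."""
    p = np.asarray(pvals, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    reject = adjusted <= q
    return adjusted, reject


def directional_count_test(
    nma_results: list[NMAResult],
    alpha: float = 0.05,
) -> tuple[int, int, GroupResult]:
    """Count individually significant sites by sign and test against chance.

    Returns (n_negative, n_positive, result) where the result is an exact
    one-sided binomial test of the total significant count against a
    per-site false-positive probability of ``alpha``.
    """
    if not nma_results:
        raise ValueError("need at least one site")
    n_neg = sum(1 for r in nma_results if r.p_two_tailed < alpha and r.z < 0)
    n_pos = sum(1 for r in nma_results if r.p_two_tailed < alpha and r.z > 0)
    k = n_neg + n_pos
    n = len(nma_results)
    test = stats.binomtest(k, n, alpha, alternative="greater")
    return n_neg, n_pos, GroupResult("directional_binomial", float(k), test.pvalue, n=n)


def group_onesample_test(values: np.ndarray, name: str = "group_onesample") -> GroupResult:
    """One-sample t-test of site-level values against zero, two-tailed."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if v.std(ddof=1) == 0:
        raise ValueError("zero variance: t undefined")
    res = stats.ttest_1samp(v, 0.0)
    return GroupResult(name, float(res.statistic), float(res.pvalue), n=v.size)
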