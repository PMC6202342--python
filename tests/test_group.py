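"""Group analyses: white-matter categories and trend, ranked contrasts,
hub terciles, frequency profiles, FDR, directional counts."""

import numpy as np
import pytest
from scipy import stats

import stimnet as sn
from stimnet.evoked import BANDS
from stimnet.group import _tercile_bins, bh_fdr, moving_average
from stimnet.nma import NMAResult


class TestClassifyWM:
    def test_median_split(self):
        cats = sn.classify_wm(np.array([1.0, 2.0, 3.0, 4.0]))
        assert list(cats) == ["near", "near", "gray", "gray"]

    def test_expert_label_precedence(self):
        cats = sn.classify_wm(np.array([1.0, 2.0, 3.0, 9.0]), np.array([False, False, False, True]))
        assert cats[3] == "in"
        assert list(cats[:3]) == ["near", "near", "gray"]

    def test_tie_policy_all_equal(self):
        with pytest.warns(UserWarning, match="equal"):
            cats = sn.classify_wm(np.array([2.0, 2.0, 2.0]))
        assert set(cats) == {"near"}

    def test_direction_flag_inverts_split(self):
        d = np.array([1.0, 2.0, 3.0, 4.0])
        inv = sn.classify_wm(d, direction="near_is_far")
        assert list(inv) == ["gray", "gray", "near", "near"]

    def test_requires_sites_to_split(self):
        with pytest.raises(ValueError):
            sn.classify_wm(np.array([1.0, 2.0]), np.array([True, True]))


class TestWMTrendPermutation:
    CATS = np.array(["gray"] * 10 + ["near"] * 10 + ["in"] * 5, dtype=object)

    def test_power_with_planted_ordering(self, rng):
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            vals = np.concatenate([
                rng.normal(0, 1, 10), rng.normal(1.5, 1, 10), rng.normal(3.0, 1, 5)
            ])
            res = sn.wm_trend_permutation_test(
                vals, self.CATS, n_perm=500, seed=int(rng.integers(2**31 - 1))
            )
            hits += res.p <= 0.05
        assert hits / n_rep >= 0.9

    def test_null_p_approximately_uniform(self, rng):
        ps = []
        for _ in range(400):
            vals = rng.normal(size=25)
            res = sn.wm_trend_permutation_test(
                vals, self.CATS, n_perm=300, seed=int(rng.integers(2**31 - 1))
            )
            ps.append(res.p)
        ks = stats.kstest(ps, "uniform").statistic
        assert ks < 0.1

    def test_degenerate_identical_values(self):
        vals = np.full(25, 3.0)
        res = sn.wm_trend_permutation_test(vals, self.CATS, n_perm=200, seed=0)
        assert res.p > 0.9

    def test_empty_category_rejected(self):
        cats = np.array(["gray", "gray", "near", "near"], dtype=object)
        with pytest.raises(ValueError, match="non-empty"):
            sn.wm_trend_permutation_test(np.zeros(4), cats, n_perm=10, seed=0)


class TestRankedConnectionContrast:
    def _setup(self, rng, n=30, t_from="conn"):
        layout = sn.generate_layout(n, seed=1)
        dist = sn.distance_network(layout)
        r = rng.uniform(0.1, 0.9, size=(n, n))
        coh = sn.AdjacencyMatrix((r + r.T) / 2, "coherence", labels=layout.labels)
        from stimnet.nma import logit

        conn = logit(np.clip(coh.values[0], 1e-6, 1 - 1e-6))
        if t_from == "conn":
            t = 2.0 * np.nan_to_num(conn) + rng.normal(0, 0.01, n)
        else:
            t = 4.0 * np.nan_to_num(dist.values[0]) + rng.normal(0, 0.3, n)
        con = sn.PowerContrast(t, 100, BANDS["theta"], labels=layout.labels)
        return con, coh, dist

    def test_connectivity_driven_effect_separates(self, rng):
        con, coh, dist = self._setup(rng, t_from="conn")
        strong, weak = sn.ranked_connection_contrast(con, coh, dist, 0)
        assert strong > weak

    def test_distance_only_effect_is_centered(self, rng):
        diffs = []
        for _ in range(100):
            con, coh, dist = self._setup(rng, t_from="dist")
            strong, weak = sn.ranked_connection_contrast(con, coh, dist, 0)
            diffs.append(strong - weak)
        mean = np.mean(diffs)
        assert abs(mean) < 3 * np.std(diffs) / np.sqrt(len(diffs)) + 0.05

    def test_needs_2k_electrodes(self, rng):
        con, coh, dist = self._setup(rng, n=12)
        mask = sn.ChannelMask(
            con.labels, np.arange(12) < 9,
            {lab: frozenset({"user"}) for lab in con.labels[9:]},
        )
        con2 = sn.PowerContrast(con.t_stat, 100, BANDS["theta"], labels=con.labels, mask=mask)
        with pytest.raises(ValueError, match="at least 10"):
            sn.ranked_connection_contrast(con2, coh, dist, 0, k=5)


class TestHubTerciles:
    def test_tercile_sizes(self):
        assert _tercile_bins(9) == (3, 3)
        assert _tercile_bins(40) == (13, 13)  # remainder to the middle bin

    def test_nine_sites_give_three_per_bin(self, rng):
        res = sn.hub_tercile_contrast(rng.uniform(0, 1, 9), rng.normal(size=9))
        assert res.n == 9
        assert np.isfinite(res.statistic)

    def test_flat_effects_rarely_significant(self, rng):
        sig = 0
        n_rep = 100
        for _ in range(n_rep):
            res = sn.hub_tercile_contrast(
                rng.uniform(0, 1, 40), rng.normal(size=40)
            )
            sig += abs(res.statistic) >= 2
        assert sig / n_rep <= 0.1

    def test_too_few_sites(self, rng):
        with pytest.raises(ValueError):
            sn.hub_tercile_contrast(np.array([0.1, 0.2]), np.array([1.0, 2.0]))


class TestBHFDR:
    def brute_force(self, p):
        """Literal step-up: adjusted p_(k) = min over j >= k of p_(j) * m / j."""
        m = len(p)
        order = np.argsort(p, kind="stable")
        adjusted = np.empty(m)
        for k, i in enumerate(order, start=1):
            candidates = [
                p[order[j - 1]] * m / j for j in range(k, m + 1)
            ]
            adjusted[i] = min(1.0, min(candidates))
        return adjusted

    def test_all_ones_rejects_nothing(self):
        adj, rej = bh_fdr(np.ones(8))
        assert not rej.any()
        np.testing.assert_array_equal(adj, np.ones(8))

    def test_uniformly_tiny_all_rejected(self):
        adj, rej = bh_fdr(np.full(10, 0.001), q=0.05)
        assert rej.all()

    def test_matches_brute_force_stepup(self, rng):
        for _ in range(10):
            p = rng.uniform(0.001, 1.0, size=17)
            adj, _ = bh_fdr(p)
            np.testing.assert_allclose(adj, self.brute_force(p), atol=1e-12)

    def test_matches_statsmodels_and_scipy(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.uniform(0.001, 1.0, size=25)
        adj, rej = bh_fdr(p, q=0.05)
        rej_sm, adj_sm, *_ = sm.multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(adj, adj_sm, atol=1e-12)
        np.testing.assert_array_equal(rej, rej_sm)
        from scipy.stats import false_discovery_control

        np.testing.assert_allclose(adj, false_discovery_control(p), atol=1e-12)

    def test_never_rejects_more_than_raw_threshold(self, rng):
        p = rng.uniform(0.0001, 1.0, size=50)
        adj, rej = bh_fdr(p, q=0.05)
        assert rej.sum() <= (p <= 0.05).sum()

    def test_rejects_invalid_pvalues(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.5]))


def _fake_result(z, p):
    return NMAResult(
        beta_conn=z, beta_dist=0.0, intercept=0.0, null_betas=np.zeros(3),
        z=z, p_two_tailed=p, n_electrodes=20, n_perm=1000, seed=0,
    )


class TestDirectionalCounts:
    def test_exact_binomial_tail(self):
        results = [_fake_result(2.5, 0.01)] * 6 + [_fake_result(-2.5, 0.01)] * 4
        results += [_fake_result(0.5, 0.6)] * 62
        n_neg, n_pos, res = sn.directional_count_test(results, alpha=0.05)
        assert (n_neg, n_pos) == (4, 6)
        expected = stats.binomtest(10, 72, 0.05, alternative="greater").pvalue
        assert res.p == pytest.approx(expected, rel=1e-12)
        assert res.p < 0.01

    def test_zero_significant_gives_p_one(self):
        results = [_fake_result(0.3, 0.8)] * 10
        _, _, res = sn.directional_count_test(results)
        assert res.p == pytest.approx(1.0)

    def test_signs_partition_count(self, rng):
        results = [
            _fake_result(float(z), float(p))
            for z, p in zip(rng.normal(size=50), rng.uniform(0.001, 1, size=50))
        ]
        n_neg, n_pos, res = sn.directional_count_test(results)
        k = sum(1 for r in results if r.p_two_tailed < 0.05)
        assert n_neg + n_pos == k


class TestGroupOneSample:
    def test_symmetric_values_give_zero_t(self):
        res = sn.group_onesample_test(np.array([-1.0, 1.0]))
        assert res.statistic == pytest.approx(0.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            sn.group_onesample_test(np.array([1.0, 1.0, 1.0]))

    def test_matches_textbook_formula(self, rng):
        v = rng.normal(0.3, 1.0, size=24)
        res = sn.group_onesample_test(v)
        t = v.mean() / (v.std(ddof=1) / np.sqrt(v.size))
        assert res.statistic == pytest.approx(t, rel=1e-12)


class TestFrequencyProfile:
    def test_smoothing_arithmetic(self):
        out = moving_average(np.array([1.0, 2.0, 3.0]), 3)
        assert out[1] == pytest.approx(2.0)

    def test_profile_shape_and_theta_peak(self):
        """Coupling confined to 5-13 Hz with a planted theta effect: the
        NMA-by-frequency profile should peak inside the coupled band."""
        spec = sn.MultitaperSpec()
        study = sn.generate_study(n_electrodes=24, n_sites=0, n_trials=2, seed=31)
        layout, coh, dist = study.layout, study.coherence, study.distance
        truth = sn.make_ground_truth(24, seed=31, beta_conn=0.08, noise_sd=0.1)
        nets = sn.per_frequency_networks(
            sn.cut_windows(study.baseline), spec, fs=1000.0, labels=layout.labels
        )
        site_inputs = []
        rng = np.random.default_rng(8)
        for stim in (3, 11, 17):
            pre, post, _ = sn.simulate_log_power_trials(
                truth, coh, dist, stim, n_trials=240, seed=int(rng.integers(2**31 - 1))
            )
            t = sn.power_contrast(np.exp(pre), np.exp(post), labels=layout.labels)
            mask = sn.apply_exclusions(layout, None, layout.contact_members[stim])
            con = sn.PowerContrast(
                t.t_stat, 240, BANDS["theta"], labels=layout.labels, mask=mask
            )
            site_inputs.append((con, nets, dist, stim))
        prof = sn.nma_frequency_profile(site_inputs, n_perm=200, seed=9)
        assert prof.freqs.size == 47
        assert prof.t_stats.size == 47 and prof.p_adjusted.size == 47
        assert np.all(prof.p_adjusted >= prof.p_raw - 1e-12)
        peak = prof.freqs[np.argmax(prof.mean_nma)]
        assert 5 <= peak <= 13

    def test_mismatched_network_lists_rejected(self, small_study):
        con = sn.PowerContrast(np.zeros(30), 10, BANDS["theta"])
        a = (con, [None] * 47, None, 0)
        b = (con, [None] * 40, None, 0)
        with pytest.raises(ValueError, match="disagree"):
            sn.nma_frequency_profile([a, b], n_perm=10, seed=0)
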