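"""Synthetic generators: determinism, planted structure, exact power synthesis."""

import numpy as np
import pytest
from scipy import stats

import stimnet as sn
from stimnet.evoked import BANDS
from stimnet.nma import logit
from stimnet.spectral import MultitaperSpec
from stimnet.synthetic import THETA_BAND, simulate_log_power_trials

SPEC = MultitaperSpec()


class TestGenerateLayout:
    def test_minimum_spacing_and_determinism(self):
        a = sn.generate_layout(60, seed=1)
        d = np.linalg.norm(
            a.coordinates[:, None] - a.coordinates[None, :], axis=-1
        )
        off = d[~np.eye(60, dtype=bool)]
        assert off.min() >= 3.5
        b = sn.generate_layout(60, seed=1)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
        np.testing.assert_array_equal(a.wm_distance, b.wm_distance)
        assert a.labels == b.labels

    def test_single_electrode_degenerate(self):
        layout = sn.generate_layout(1, seed=0)
        assert layout.n_electrodes == 1

    def test_rejects_nonpositive_count(self):
        with pytest.raises(ValueError):
            sn.generate_layout(0, seed=0)

    def test_flags_and_wm_distances(self):
        layout = sn.generate_layout(40, seed=2)
        assert np.all(layout.wm_distance >= 0)
        assert layout.soz.sum() == 4  # 10% of 40
        assert layout.in_wm.sum() == 4


class TestGenerateBaseline:
    def test_shared_source_gives_high_coherence(self):
        layout = sn.generate_layout(2, seed=0)
        truth = sn.GroundTruth(
            mixing_weights=np.array([[5.0, 5.0]]), source_freqs=[8.0]
        )
        rec = sn.generate_baseline(layout, truth, n_periods=10, seed=1,
                                   channel_noise_sd=0.5)
        net = sn.coherence_network(sn.cut_windows(rec), SPEC, fs=1000.0, band=(7.5, 8.5))
        assert net.values[0, 1] > 0.9

    def test_zero_mixing_stays_at_bias_floor(self):
        layout = sn.generate_layout(4, seed=0)
        truth = sn.GroundTruth(mixing_weights=np.zeros((1, 4)), source_freqs=[8.0])
        rec = sn.generate_baseline(layout, truth, n_periods=10, seed=1)
        net = sn.coherence_network(sn.cut_windows(rec), SPEC, fs=1000.0)
        off = net.values[~np.eye(4, dtype=bool)]
        assert np.nanmax(off) <= 0.2

    def test_determinism_and_nyquist_guard(self):
        layout = sn.generate_layout(3, seed=0)
        truth = sn.make_ground_truth(3, seed=0)
        a = sn.generate_baseline(layout, truth, n_periods=2, seed=5)
        b = sn.generate_baseline(layout, truth, n_periods=2, seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)
        bad = sn.GroundTruth(mixing_weights=np.ones((1, 3)), source_freqs=[600.0])
        with pytest.raises(ValueError, match="Nyquist"):
            sn.generate_baseline(layout, bad, n_periods=1, fs=1000.0, seed=0)


@pytest.fixture(scope="module")
def networks():
    """Layout + estimated coherence/distance shared by session tests."""
    study = sn.generate_study(n_electrodes=30, n_sites=0, n_trials=2, seed=21)
    return study.layout, study.truth, study.coherence, study.distance


class TestGenerateStimSession:
    def test_segment_power_reproduces_drawn_log_power(self, networks):
        layout, truth, coh, dist = networks
        sess = sn.generate_stim_session(
            layout, coh, dist, truth, layout.labels[4], n_trials=8, seed=42
        )
        # replay the generator's draws
        rng = np.random.default_rng(42)
        pre_log, post_log, _ = simulate_log_power_trials(
            truth, coh, dist, 4, n_trials=8, rng=rng
        )
        pre_meas = sn.band_power_matrix(sess.pre, THETA_BAND, SPEC, sess.fs)
        post_meas = sn.band_power_matrix(sess.post, THETA_BAND, SPEC, sess.fs)
        np.testing.assert_allclose(np.log(pre_meas), pre_log, rtol=1e-9)
        np.testing.assert_allclose(np.log(post_meas), post_log, rtol=1e-9)

    def test_determinism(self, networks):
        layout, truth, coh, dist = networks
        a = sn.generate_stim_session(layout, coh, dist, truth, layout.labels[4],
                                     n_trials=4, seed=1)
        b = sn.generate_stim_session(layout, coh, dist, truth, layout.labels[4],
                                     n_trials=4, seed=1)
        np.testing.assert_array_equal(a.pre, b.pre)
        np.testing.assert_array_equal(a.post_art, b.post_art)
        np.testing.assert_array_equal(a.pulse_freqs, b.pulse_freqs)

    def test_strong_effect_ranks_match_connectivity(self, networks):
        """In the near-noiseless limit the t-statistic rank order follows
        logit coherence when the distance effect is off."""
        layout, truth_base, _, dist = networks
        rng = np.random.default_rng(13)
        r = rng.uniform(0.05, 0.95, size=(30, 30))
        coh = sn.AdjacencyMatrix((r + r.T) / 2, "coherence", labels=layout.labels)
        truth = sn.GroundTruth(
            mixing_weights=truth_base.mixing_weights,
            source_freqs=truth_base.source_freqs,
            beta0=0.0, beta_conn=0.2, beta_dist=0.0, noise_sd=0.02,
        )
        stim = 4
        sess = sn.generate_stim_session(layout, coh, dist, truth,
                                        layout.labels[stim], n_trials=240, seed=3)
        con = sn.session_power_contrast(sess, BANDS["theta"])
        others = np.arange(30) != stim
        rho = stats.spearmanr(
            con.t_stat[others],
            logit(np.clip(coh.values[stim, others], 0, 1)),
        ).statistic
        assert rho >= 0.9

    def test_trial_structure(self, networks):
        layout, truth, coh, dist = networks
        sess = sn.generate_stim_session(layout, coh, dist, truth,
                                        layout.labels[0], n_trials=240, seed=0)
        assert sess.n_trials == 240
        assert np.all(np.diff(sess.onsets) >= 3.0)  # >= 3 s between events
        assert sess.stim_duration == 0.5
        # 60-trial amplitude blocks, 12 trials per pulse frequency per block
        assert set(np.unique(sess.amplitudes[:60])) == {0.5}
        freq_counts = np.unique(sess.pulse_freqs[:60], return_counts=True)[1]
        assert np.all(freq_counts == 12)

    def test_rejects_bad_inputs(self, networks):
        layout, truth, coh, dist = networks
        with pytest.raises(ValueError, match="n_trials"):
            sn.generate_stim_session(layout, coh, dist, truth, layout.labels[0],
                                     n_trials=1, seed=0)
        with pytest.raises(KeyError):
            sn.generate_stim_session(layout, coh, dist, truth, ("no", "pe"),
                                     n_trials=4, seed=0)


class TestInjectArtifact:
    def test_identity_when_no_change(self, networks):
        layout, truth, coh, dist = networks
        sess = sn.generate_stim_session(layout, coh, dist, truth, layout.labels[0],
                                        n_trials=4, seed=0)
        out = sn.inject_artifact(sess, [1, 2], offset_uv=0.0, var_factor=1.0)
        np.testing.assert_array_equal(out.post_art, sess.post_art)
        np.testing.assert_array_equal(out.pre, sess.pre)

    def test_offset_flagged_by_detector(self, networks):
        layout, truth, coh, dist = networks
        sess = sn.generate_stim_session(layout, coh, dist, truth, layout.labels[0],
                                        n_trials=240, seed=1)
        out = sn.inject_artifact(sess, [3], offset_uv=50.0)
        mask = sn.detect_artifact_channels(out)
        assert not mask.included[3]

    def test_variance_factor_flagged_by_levene_branch(self, networks):
        layout, truth, coh, dist = networks
        sess = sn.generate_stim_session(layout, coh, dist, truth, layout.labels[0],
                                        n_trials=240, seed=2)
        out = sn.inject_artifact(sess, ["C5-C6"], offset_uv=0.0, var_factor=4.0)
        mask = sn.detect_artifact_channels(out)
        assert not mask.included[out.labels.index("C5-C6")]

    def test_unknown_channel_rejected(self, networks):
        layout, truth, coh, dist = networks
        sess = sn.generate_stim_session(layout, coh, dist, truth, layout.labels[0],
                                        n_trials=4, seed=0)
        with pytest.raises(KeyError):
            sn.inject_artifact(sess, ["NOPE"], offset_uv=1.0)
        with pytest.raises(IndexError):
            sn.inject_artifact(sess, [999], offset_uv=1.0)


class TestGroundTruthInvariants:
    def test_validation(self):
        with pytest.raises(ValueError, match="noise_sd"):
            sn.GroundTruth(np.ones((1, 2)), [8.0], noise_sd=0.0)
        with pytest.raises(ValueError, match="finite"):
            sn.GroundTruth(np.array([[np.inf, 1.0]]), [8.0])
        bad_coupling = np.array([[1.0, 0.5], [0.4, 1.0]])  # asymmetric
        with pytest.raises(ValueError, match="envelope_coupling"):
            sn.GroundTruth(np.ones((1, 2)), [8.0], envelope_coupling=bad_coupling)

    def test_study_channel_consistency(self, small_study):
        n = small_study.layout.n_electrodes
        assert small_study.baseline.n_channels == n
        assert all(s.n_channels == n for s in small_study.sessions)
        assert small_study.truth.seed is not None


class TestHFBRest:
    def test_grouped_channels_comodulate(self):
        rec = sn.generate_hfb_rest(3, groups=[[0, 1]], duration_s=60.0, seed=0)
        with pytest.warns(UserWarning, match="240"):
            net = sn.hfb_envelope_network(rec)
        assert net.values[0, 1] > net.values[0, 2]
        assert net.values[0, 1] > net.values[1, 2]

    def test_determinism(self):
        a = sn.generate_hfb_rest(2, groups=[[0, 1]], duration_s=40.0, seed=5)
        b = sn.generate_hfb_rest(2, groups=[[0, 1]], duration_s=40.0, seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)
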