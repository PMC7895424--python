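"""Phase coherence, surrogate inference, FDR, classification, latency, ROI."""

import numpy as np
import pytest

import seqtag as st
from seqtag.recording import ChannelInfo
from seqtag.tagging import (
    TrialTensor,
    apply_fdr,
    fdr_correct,
    latency_analysis,
    roi_enrichment,
    spatial_grouping_bayes,
)

UNIT_HZ = 4 / 3


def make_trials(values, rate=250.0, condition="structured"):
    values = np.asarray(values, dtype=float)
    chans = [ChannelInfo(id=f"c{i}") for i in range(values.shape[2])]
    return TrialTensor(
        values=values,
        rate_hz=rate,
        segment_units=10,
        segment_duration_s=values.shape[1] / rate,
        condition=condition,
        field_type="fp",
        channels=chans,
    )


def trials_from_phases(phases, f_hz=UNIT_HZ, n_samples=1875, rate=250.0):
    """Trials whose DFT phase at f_hz equals the given (trials x channels) array."""
    t = np.arange(n_samples) / rate
    vals = np.cos(
        2 * np.pi * f_hz * t[None, :, None] + phases[:, None, :]
    )
    return make_trials(vals, rate=rate)


class TestSegmentation:
    def test_five_blocks_make_90_trials(self, entrained_trials):
        assert entrained_trials.n_trials == 90
        assert entrained_trials.n_samples == 1875
        assert entrained_trials.freq_resolution_hz == pytest.approx(2 / 15)

    def test_probed_stream_still_90_trials(self, inventory):
        s = st.generate_structured_stream(inventory, 5, 540, seed=1)
        p = st.embed_one_back_probes(s, 16, seed=2)
        rec = st.synthesize_recording(p, [st.ChannelSpec(id="a")], seed=0)
        trials = st.segment_trials(rec, p)
        assert trials.n_trials == 90

    def test_short_stream_raises(self, inventory):
        s = st.generate_structured_stream(inventory, 1, 9, seed=1)
        rec = st.synthesize_recording(s, [st.ChannelSpec(id="a")], seed=0)
        with pytest.raises(ValueError, match="segment"):
            st.segment_trials(rec, s)


class TestPhaseExtraction:
    def test_cosine_has_zero_phase(self):
        phases = np.zeros((5, 2))
        trials = trials_from_phases(phases)
        out = st.phase_at_frequency(trials, UNIT_HZ)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_sine_has_minus_half_pi_phase(self):
        phases = np.full((4, 1), -np.pi / 2)
        trials = trials_from_phases(phases)
        out = st.phase_at_frequency(trials, UNIT_HZ)
        assert np.allclose(out, -np.pi / 2, atol=1e-9)

    def test_matches_naive_dft_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((3, 750, 2))
        trials = make_trials(vals)
        f = 4.0
        out = st.phase_at_frequency(trials, f)
        # independent oracle: direct inner product with the DFT basis vector
        n = vals.shape[1]
        k = int(round(f * n / 250.0))
        basis = np.exp(-2j * np.pi * k * np.arange(n) / n)
        expected = np.angle(np.einsum("tsc,s->tc", vals, basis))
        assert np.allclose(out, expected)

    def test_off_bin_frequency_raises(self):
        trials = make_trials(np.zeros((2, 1875, 1)))
        with pytest.raises(ValueError, match="nearest bins"):
            st.phase_at_frequency(trials, 1.3)


class TestCoherence:
    def test_identical_phases_give_plv_one(self):
        phases = np.full((8, 1), 0.7)
        trials = trials_from_phases(phases)
        coh = st.coherence_spectrum(trials)
        k = int(round(UNIT_HZ * trials.segment_duration_s))
        assert coh.plv[0, k] == pytest.approx(1.0, abs=1e-9)
        assert coh.R[0, k] == pytest.approx(8.0, abs=1e-6)

    def test_uniform_phases_cancel(self):
        n = 8
        phases = (2 * np.pi * np.arange(n) / n)[:, None]
        trials = trials_from_phases(phases)
        coh = st.coherence_spectrum(trials)
        k = int(round(UNIT_HZ * trials.segment_duration_s))
        assert coh.plv[0, k] == pytest.approx(0.0, abs=1e-9)

    def test_matches_unit_vector_sum_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((6, 750, 3))
        trials = make_trials(vals)
        coh = st.coherence_spectrum(trials)
        spec = np.fft.rfft(vals, axis=1)
        expected = np.abs(np.exp(1j * np.angle(spec)).sum(axis=0)).T
        assert np.allclose(coh.R, expected)
        assert np.allclose(coh.plv, expected / 6)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError, match="2 trials"):
            st.coherence_spectrum(make_trials(np.zeros((1, 750, 1))))

    def test_plv_invariant_to_common_offset(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(-np.pi, np.pi, size=(7, 1))
        t0 = trials_from_phases(base)
        t1 = trials_from_phases(base + 1.234)
        k = int(round(UNIT_HZ * t0.segment_duration_s))
        p0 = st.coherence_spectrum(t0).plv[0, k]
        p1 = st.coherence_spectrum(t1).plv[0, k]
        assert p0 == pytest.approx(p1, abs=1e-9)


class TestSurrogates:
    def test_frequency_domain_shift_equals_literal_roll(self):
        """The phase-rotation shortcut must agree exactly with circularly
        shifting the data and re-running the FFT."""
        rng = np.random.default_rng(3)
        vals = rng.standard_normal((4, 300, 2))
        trials = make_trials(vals)
        f = 5.0
        k = int(round(f * trials.segment_duration_s))
        phases = st.phase_at_frequency(trials, f)
        shifts = rng.integers(0, 300, size=4)
        # implementation convention: delay by s samples, x[t] -> x[t - s]
        rolled = np.stack(
            [np.roll(vals[i], shifts[i], axis=0) for i in range(4)]
        )
        expected = np.angle(np.fft.rfft(rolled, axis=1))[:, k, :]
        shortcut = np.angle(
            np.exp(1j * phases) * np.exp(-2j * np.pi * k * shifts / 300)[:, None]
        )
        assert np.allclose(
            np.exp(1j * shortcut), np.exp(1j * expected), atol=1e-10
        )

    def test_entrained_channel_reaches_minimum_p(self, entrained_trials):
        res = st.surrogate_test(entrained_trials, n_surrogates=1000, seed=0)
        i_upt = 0  # unit_plus_token channel
        assert res.p_raw[i_upt, 0] == pytest.approx(1 / 1001)
        assert res.p_raw[i_upt, 1] == pytest.approx(1 / 1001)

    def test_zero_surrogates_rejected(self, entrained_trials):
        with pytest.raises(ValueError, match="n_surrogates"):
            st.surrogate_test(entrained_trials, n_surrogates=0)


class TestFDR:
    def test_hand_computed_bh_oracle(self):
        # step-up: adjusted = min over j>=i of p_(j) * m / j
        adj, flags = fdr_correct(np.array([0.01, 0.02, 0.03, 0.04]), alpha=0.05)
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])
        assert flags.all()

    def test_all_ones_never_flagged(self):
        adj, flags = fdr_correct(np.ones(10))
        assert np.all(adj == 1.0)
        assert not flags.any()

    def test_single_p_unchanged(self):
        adj, flags = fdr_correct(np.array([0.03]), alpha=0.05)
        assert adj[0] == pytest.approx(0.03)
        assert flags[0]

    def test_adjusted_at_least_raw_and_within_subject(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=20)
        subjects = ["A"] * 10 + ["B"] * 10
        adj, _ = fdr_correct(p, subjects=subjects)
        assert np.all(adj >= p - 1e-12)
        # correction in one subject is unaffected by the other's p-values
        adj_a, _ = fdr_correct(p[:10])
        assert np.allclose(adj[:10], adj_a)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct(np.array([1.2]))


class TestClassification:
    def test_ground_truth_classes_recovered(self, entrained_trials):
        tagger = st.CoherenceTagger(n_surrogates=500, random_state=0).fit(entrained_trials)
        classes = tagger.predict()
        assert classes[:3] == ["unit_plus_token", "unit_only", "nonresponsive"]
        # the token-tracking channel is flagged token_only, not unit-responsive
        assert tagger.classification_.token_only[2]
        # the pure-noise channel never reaches unit-rate significance
        unit_col = tagger.result_.freq_index(UNIT_HZ)
        assert not tagger.significant_[3, unit_col]

    def test_classification_requires_flags(self, entrained_trials):
        res = st.coherence_spectrum(entrained_trials)
        with pytest.raises(ValueError, match="FDR"):
            st.classify_channels(res)


class TestLatency:
    def test_entrained_channel_found_early(self, entrained_trials):
        sub = make_trials(entrained_trials.values[:, :, [0, 3]])
        lat = latency_analysis(sub, alpha=0.05)
        assert lat.ks[0] == 2  # k=1 undefined, skipped
        first = lat.first_significant_trial
        assert 0 < first[0] <= 10
        # the entrained channel's Rayleigh p collapses as phases accumulate
        assert lat.p_trajectory[0, -1] < 1e-6

    def test_all_null_set_rarely_flagged(self):
        """Across the whole sequential analysis, pure-noise channels reach
        significance only at roughly the FDR level."""
        from seqtag.simulate import pink_noise

        rng = np.random.default_rng(0)
        vals = np.stack(
            [pink_noise(90 * 1875, rng).reshape(90, 1875) for _ in range(20)],
            axis=2,
        )
        lat = latency_analysis(make_trials(vals))
        assert (lat.first_significant_trial > 0).sum() <= 2

    def test_higher_snr_is_earlier(self, long_structured_stream):
        firsts = []
        for snr in (0.25, 1.0):
            spec = [
                st.ChannelSpec(id=f"s{i}", ground_truth_class="unit_only", snr=snr,
                               learn_midpoint_units=0.0, learn_scale_units=1.0)
                for i in range(4)
            ]
            rec = st.synthesize_recording(long_structured_stream, spec, seed=9)
            trials = st.segment_trials(rec, long_structured_stream)
            lat = latency_analysis(trials)
            found = lat.first_significant_trial
            firsts.append(found[found > 0].mean())
        assert firsts[1] <= firsts[0]


class TestROI:
    def test_odds_ratio_oracle(self):
        cls = _classification(["A"] * 10 + ["B"] * 10,
                              ["unit_only"] * 5 + ["nonresponsive"] * 5
                              + ["unit_only"] * 1 + ["nonresponsive"] * 9)
        props, ors = roi_enrichment(cls)
        assert props.loc["A", "proportion"] == 0.5
        assert props.loc["B", "proportion"] == 0.1
        row = ors.iloc[0]
        assert row["odds_ratio"] == pytest.approx((5 / 5) / (1 / 9))

    def test_equal_proportions_give_unit_or(self):
        cls = _classification(["A"] * 4 + ["B"] * 4,
                              (["unit_only", "nonresponsive"] * 4))
        _, ors = roi_enrichment(cls)
        assert ors.iloc[0]["odds_ratio"] == pytest.approx(1.0)

    def test_zero_cell_uses_haldane_correction(self):
        cls = _classification(["A"] * 4 + ["B"] * 4,
                              ["unit_only"] * 4 + ["nonresponsive"] * 4)
        _, ors = roi_enrichment(cls)
        assert np.isfinite(ors.iloc[0]["odds_ratio"])
        assert ors.iloc[0]["odds_ratio"] == pytest.approx((4.5 / 0.5) / (0.5 / 4.5))

    def test_single_roi_raises(self):
        cls = _classification(["A"] * 4, ["unit_only"] * 4)
        with pytest.raises(ValueError, match="2 ROIs"):
            roi_enrichment(cls)


def _classification(rois, classes):
    chans = [ChannelInfo(id=f"c{i}", roi=r) for i, r in enumerate(rois)]
    return st.tagging.ChannelClassification(
        channels=chans,
        classes=list(classes),
        token_only=np.zeros(len(chans), dtype=bool),
        unit_hz=UNIT_HZ,
        token_hz=4.0,
    )


class TestSpatialBayes:
    def test_separated_clusters_give_large_bf(self):
        coords = np.vstack(
            [np.random.default_rng(0).normal(0, 1, (10, 3)),
             np.random.default_rng(1).normal(100, 1, (10, 3))]
        )
        labels = ["x"] * 10 + ["y"] * 10
        log_bf, info = spatial_grouping_bayes(labels, coords)
        assert info["same_type"] == 20
        assert log_bf > 5

    def test_matches_beta_binomial_quadrature_oracle(self):
        from scipy import integrate, stats as sps

        rng = np.random.default_rng(2)
        coords = rng.normal(0, 1, (12, 3))
        labels = ["x"] * 6 + ["y"] * 6
        log_bf, info = spatial_grouping_bayes(labels, coords)
        n, x, p0 = info["n"], info["same_type"], info["p0"]
        num, _ = integrate.quad(
            lambda p: sps.binom.pmf(x, n, p) / (1 - p0), p0, 1.0
        )
        expected = np.log(num / sps.binom.pmf(x, n, p0))
        assert log_bf == pytest.approx(expected, abs=1e-6)

    def test_shuffled_labels_near_zero_on_average(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(0, 1, (30, 3))
        vals = []
        for i in range(20):
            labels = np.array(["x"] * 15 + ["y"] * 15)
            rng.shuffle(labels)
            log_bf, _ = spatial_grouping_bayes(list(labels), coords)
            vals.append(log_bf)
        assert abs(np.mean(vals)) < 2.0

    def test_one_channel_of_a_type_raises(self):
        with pytest.raises(ValueError, match=">= 2"):
            spatial_grouping_bayes(["x", "y", "y"], np.zeros((3, 3)))
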